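# Methods

## Scope and data model

The package operates on per-specimen observation tables: one row per
ocellus seen on one side of a carapace, with a 2-D position, a relative
diameter and taxon bookkeeping. Three printed survey tables (eyeless
taxa; per-family sampling depth; eyespot records) ship as TSV
transcriptions and are tabulated with cross-checks against their own
printed totals.

**Coordinate frame.** No quantitative carapace coordinate system exists
in the source material; positions here live in a per-side dimensionless
frame, `ap` in [0, 1] increasing anterior → posterior and `dv`
increasing ventral → dorsal. This frame is a convention of the package:
all inference uses only *relative* positions (angular sectors between
ocelli), so any monotone affine re-expression of the raw coordinates
leaves the labels unchanged. Dextral sides are mirrored into the frame
on ingest (`ap ← 1 − ap`, with rounding at nine decimals so the mirror
is an involution on tabulated precision), making downstream geometry
side-agnostic.

**Diameters** are expressed relative to the largest ocellus of the same
side (largest = 1.0), since only relative size carries information.

**Eyespots** — lensless photosensitive spots posteroventral/ventral to
the lateral ocelli — are structurally and functionally distinct from
ocelli. They are carried as side-level tri-state evidence
(present/absent/unknown) and never receive an ocellus identity; rows
with `lens_present = false` are routed to eyespot evidence on ingest.
Unscorable taxa (pale, immaculate integument) stay `unknown`, which maps
to missing data (`?`) in character matrices, never to absence.

## Homology assignment

Identity assignment composes three rules; the composition is
deterministic for a fixed configuration and every assignment carries a
confidence flag (`firm` or `tie_broken`).

1. **Tier split.** Observations are sorted by descending diameter and
   split at the first multiplicative gap exceeding
   `major_minor_ratio` (default 1.5), capped at four majors. The first
   qualifying gap — not the largest — is used: the minor tier has
   sizeable internal gaps of its own (PDMi can be nearly twice PLMi), and
   a largest-gap rule would capture PDMi into the major tier on
   four-ocellus sides with PLMi. With no qualifying gap, one or two
   similar ocelli are all majors (the two-major patterns dominate that
   regime); three or four gap-free ocelli are treated the same way but
   flagged `tie_broken`.
2. **Major row.** The *k* ≤ 4 majors, ordered by `ap`, take the
   posterior-most *k* of (AALMa, ALMa, MLMa, PLMa). This builds the
   observed coincidence chain (ALMa only ever occurs with MLMa and PLMa,
   MLMa only with PLMa, AALMa only with ALMa) into every output.
   Supernumerary majors beyond four are left unassigned and the side is
   flagged abnormal.
3. **Minor sectors.** The plane around the PLMa anchor is divided into
   eight 45° sectors with boundaries offset 22.5° from the compass
   directions (posterior = +ap, dorsal = +dv). The sector vocabulary is
   qualitative in the source tradition; the 45° geometry is this
   package's quantitative rendering and is configurable. ADMi may lie
   anterodorsal/dorsal/posterodorsal of PLMa; PDMi
   dorsal/posterodorsal/posterior; with both present the anterior one is
   ADMi. A lone minor in the dorsal/posterodorsal overlap defaults to
   PDMi — by far the most prevalent minor — and is flagged `tie_broken`;
   a lone anterodorsal minor is a firm ADMi. PLMi is the minor ventral to
   PDMi (and posterior to PLMa); remaining posteroventral satellites of
   PDMi are accessory APLMi, numbered 1–3 by increasing distance from
   PDMi (the tradition gives size relations but no ordering rule;
   distance is this package's choice). Minors failing every sector
   constraint, or present without the anchor they need, are left
   unassigned and flagged.

Size orderings beyond the tier split are treated as soft evidence only:
position takes precedence, because the reported exceptions to the size
chain (e.g. ADMi larger than PDMi in several buthid subfamilies) are
positional non-exceptions.

**PDMi position classes.** For sides with the full three-major row, the
dorsal offset of PDMi from the least-squares row axis is banded into the
three classical positions of the buthid fourth ocellus: P1 (in the row
plane, |offset| ≤ 0.03), P2 (on the carapace ridge, ≤ 0.10), P3 (above
it). Whether "on" versus "above" a ridge is decidable from coordinates
alone is doubtful; the dv-band is a stated proxy and both edges are
configurable.

## Patterns and the loss lattice

Eleven defined member sets exist (six-ocellus root, Types 5, 4A, 4B, 4C,
3A, 3B, 2A, 2B, 1, eyeless). Classification strips accessory identities
first — accessory ocelli are outside the model, so their presence makes
the side ABNORMAL while the non-accessory residual is still reported —
then matches the residual exactly. The classifier is total over all 2¹⁰
identity subsets, and exactly 11 subsets map to defined patterns (the
accessory-free member sets themselves). Twelve derivation edges connect
the defined patterns; `is_reduction` is member-set inclusion and agrees
with lattice reachability. The six-ocellus root is kept as a theoretical
construct: no surveyed individual showed all ten, or even all six,
identities at once on one side. No probabilistic ancestral-state
reconstruction is performed on the lattice.

## Bilateral reconciliation and aggregation

Ocelli are assumed bilaterally symmetric; with unequal counts the lesser
side is interpreted as a subset of the greater, and the individual's
complement is the union of its sides. Positional differences alone never
break homology. Sides that are mutually non-nested are *discordant* (a
rare condition, observed in an *Opistophthalmus* species); they still
contribute their union and count as asymmetric. Species aggregation
builds a morph table from complements; a species is polymorphic when its
morphs span ≥ 2 distinct ocellus counts, and a nestedness flag records
whether lesser morphs are subsets of greater ones (the dominant mode).
The modal pattern is the most frequent defined pattern among
complements, ties going to the pattern with more ocelli since lesser
morphs read as reductions.

**Denominators.** Asymmetry is only observable on two-sided specimens,
and only expressible by ocellus-bearing ones; the survey report
therefore exposes the asymmetric count against three denominators (all
individuals, two-sided individuals, sighted individuals) rather than
committing to one. Fractions are always recomputed from integer counts;
nothing rounded is stored.

## Character matrices

Species are coded as 11 binary characters — the ten identities in
canonical order (AALMa, ALMa, MLMa, PLMa, ADMi, PDMi, PLMi, APLMi₁–₃)
plus the eyespot — because identity-level presence is more informative
than ocellus counts. A character is 1 when every individual of the
species carries the identity, 0 when none does, `{01}` in between;
eyespot `unknown` is `?`. Accessory characters are retained even when
all-absent so indices stay stable. Writers produce a standard-datatype
NEXUS DATA block and a TNT `xread` with the same cell model; the NEXUS
writer/reader pair round-trips randomized matrices identically, and the
written files also parse under dendropy. Characters are exported
unordered; a step-matrix rendering of the loss lattice is future work.

## Synthetic surveys

The generator's defaults are the study conditions of the reference
survey, not tuning knobs:

* **Sampling plan** — one entry per exemplar species, rebuilt from the
  packaged sampling table: 19 families, 160 genera, 196 species, 519
  individuals, 71 singleton species, at most 12 individuals per species.
  Singletons are allotted per family proportionally (clamped to keep
  multi-individual species between 2 and 12).
* **Pattern priors** — per-family frequencies of the general patterns
  among exemplar species, transcribed from the reported taxonomic
  distribution (Type 5 only in Buthidae and dominant there; Type 4C
  dominant among chactoids; Type 4B in Scorpionidae/Scorpiopidae; Type
  2A in Chaerilidae; Type 1 confined to Pseudochactidae; eyeless
  Akravidae and Typhlochactidae; etc.). Shares may jointly exceed 100 %
  of a family (species can present several patterns) and are normalized
  into a prior.
* **Geometry** — positions are identity templates plus isotropic
  Gaussian jitter (`position_noise_sd`, default 0.01 ≈ 1 % of carapace
  length). Templates sit at the centres of their sector decision
  regions, so every template has the half-sector (22.5°) margin that the
  robustness guarantee assumes. The graphical positional-variation
  ranges of the minors are approximated by this jitter and are
  configurable.
* **Sizes** — uniform draws from per-identity bands whose midpoints (and
  in the core model, whole bands) honour the size-inequality chain
  AALMa < ALMa < MLMa > PLMa > PDMi > ADMi, PDMi > PLMi.
* **Asymmetry** — with probability 0.11 an individual loses one ocellus
  on one random side, the dominant observed mode (subset asymmetry).
  Losses are restricted to ocelli whose removal leaves a positionally
  identifiable remainder (anterior-most major; ADMi; PDMi when no
  posterior satellite depends on it; PLMi; PLMa when alone): since
  identities are *defined* by relative position, a loss that makes the
  remainder read as a different identity set is not an observable
  single-loss asymmetry under the model. Discordant individuals are an
  optional mode, off by default. Eyeless individuals cannot express
  asymmetry, so the recovered rate is calibrated on the sighted
  denominator.
* **Polymorphism** — species sampled with ≥ 2 individuals carry a
  second, one-step-reduced morph with probability 0.33, chosen so that
  the realized polymorphic share of *all* species is ≈ 0.33 × 125/196 ≈
  21 %, matching the reference survey's 42/196; only multi-individual
  species can express polymorphism, and carriers always express both
  morphs. Ground truth records the realized morphs, row-aligned with the
  emitted table.
* **Eyespots** — drawn per individual from per-family tri-state priors
  (eyespot-bearing families get presence mass; Chaerilidae nearly
  always present; pale taxa contribute `unknown`), independent of the
  ocellus pattern, for which no dependency is reported.
* **Seeding** — one master seed; each species draws from an independent
  substream keyed by its name, so adding a species never perturbs
  another's draws.

## What the synthetic tests do and do not show

Zero-noise surveys are recovered exactly — labels, patterns, symmetry
and polymorphism flags — which validates the pipeline's logic, and the
thirty-survey calibration shows the recovered asymmetric share of
sighted individuals sits within one percentage point of the configured
0.11. Real specimens differ in ways the generator does not emulate:
granulation and infuscation that hide minor ocelli, damaged or
single-sided specimens, subfamily-specific size reversals (ADMi > PDMi),
carapace compression shifting PDMi posteriorly, and continuous
positional variation not centred on any template. Passing tests
therefore demonstrate internal consistency of the model and rules, not
field-ready scoring accuracy. The reference survey's absolute tallies
(58 asymmetric individuals, 42 polymorphic species) require its raw
specimen data, which is not machine-readable; the calibration above is
the package's stand-in, and the simulated counts land on the same scale
(≈ 54 and ≈ 40 on average).

## Numerical choices and degenerate inputs

Problem sizes in tests and the acceptance script — 519 individuals per
survey, 30 calibration seeds, 100 round-trip matrices, exhaustive 2¹⁰
classifier census — are the package's chosen verification scale and run
in seconds. Empty sides label to the empty set; empty fixture tables
tally zero; a side with more than ten observations, a non-positive
diameter, duplicate observation keys, unknown state vocabulary, mixed
species in aggregation and duplicate taxon labels in matrices all raise
typed validation errors rather than coercing. Tie-breaks and
discordances are logged by the CLI, and all thresholds (sector offset,
size ratio, similarity tolerance, position-class band edges) live in a
single configuration object readable from YAML.
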