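# sixocellus

Homology assignment, pattern classification and phylogenetic character
coding for the lateral eyes of scorpions.

## The problem

Scorpions carry zero to five-plus pairs of small lateral ocelli on the
anterolateral carapace. Their *number* varies within families, within
genera and even within species, which long made lateral-ocellus counts
look useless for systematics. Counts, however, conceal combinations: two
different four-ocellus conditions can be different characters. Under a
six-ocellus model the full complement comprises three **major** ocelli in
an anteroposterior row — ALMa, MLMa, PLMa — and three **minor**
satellites — ADMi, PDMi, PLMi — with four rarely seen **accessory**
ocelli (AALMa, APLMi₁–₃) outside the model. Each observed ocellus can be
assigned one of these identities from *relative* position and size
alone, and presence/absence of identities, not counts, becomes the
phylogenetic character.

This package is for systematists and morphologists who score ocelli from
specimens (or want to test scoring protocols): it turns per-specimen
observation tables into labeled ocelli, named patterns, reconciled
individuals, species summaries and NEXUS/TNT matrices.

## The model

* **Size tiers.** Majors are mutually similar and, with few exceptions,
  larger than minors; the tier split goes at the first diameter gap
  exceeding a ratio *r* (default 1.5) in the descending sequence.
* **Major row.** With *k* ≤ 4 majors, the posterior-most *k* of
  (AALMa, ALMa, MLMa, PLMa) are assigned in ap order, so the coincidence
  chain ALMa ⟹ MLMa ⟹ PLMa and AALMa ⟹ ALMa holds by construction.
* **Minor sectors.** Minors are placed by 45° angular sector relative to
  PLMa: ADMi anterodorsal/dorsal/posterodorsal, PDMi
  dorsal/posterodorsal/posterior, PLMi posterior to PLMa and ventral to
  PDMi, APLMi₁–₃ posteroventral to PDMi numbered by distance. A lone
  dorsal-region minor defaults to PDMi (the most prevalent minor) and is
  flagged `tie_broken`.
* **Patterns.** The identity set of a side maps to exactly one of twelve
  outcomes: the six-ocellus root, nine named reductions (Types 5, 4A–4C,
  3A–3B, 2A–2B, 1), the eyeless state, or ABNORMAL (any other set, and
  any set containing an accessory ocellus). Twelve loss edges connect
  the defined patterns into a derivation lattice.
* **Bilateral rule.** Sides of one individual are assumed to share a
  complement; with unequal counts the lesser side is a subset of the
  greater, and the individual's complement is the union.

A synthetic-data module generates whole surveys with the structure of
the reference order-wide survey (19 families, 196 species, 519
individuals; ~11 % asymmetric individuals; ~21 % polymorphic species)
together with per-observation ground truth, so the entire pipeline is
testable end to end.

## Worked example

```python
from sixocellus import OcellusObservation, SideRecord, label_side, pattern_of

side = SideRecord(
    side="sinistral",
    observations=[
        OcellusObservation(ap=0.20, dv=0.00, diameter=0.90),
        OcellusObservation(ap=0.38, dv=0.00, diameter=1.00),
        OcellusObservation(ap=0.56, dv=0.00, diameter=0.92),
        OcellusObservation(ap=0.48, dv=0.08, diameter=0.40),
        OcellusObservation(ap=0.64, dv=0.08, diameter=0.50),
    ],
)
labeled = label_side(side)
call = pattern_of(labeled.identity_set)
```

Running `python examples/02_label_one_side.py` prints:

```
obs 0: ap=0.20 dv=+0.00 d=0.90 -> ALMa (firm)
obs 1: ap=0.38 dv=+0.00 d=1.00 -> MLMa (firm)
obs 2: ap=0.56 dv=+0.00 d=0.92 -> PLMa (firm)
obs 3: ap=0.48 dv=+0.08 d=0.40 -> ADMi (firm)
obs 4: ap=0.64 dv=+0.08 d=0.50 -> PDMi (firm)
pattern: T5 with 5 ocelli
```

The three in-row ocelli split into the major tier (the 0.92→0.40 gap
exceeds 1.5×) and read ALMa–MLMa–PLMa front to back; the two satellites
land in the anterodorsal and posterodorsal sectors of PLMa, giving ADMi
and PDMi. The set {ALMa, MLMa, PLMa, ADMi, PDMi} is Type 5 — the
commonest buthid condition, with PLMi absent.

The other scripts in `examples/` walk the remaining capabilities:
fixture tabulation, the pattern lattice, survey simulation and
ground-truth recovery, survey statistics, and matrix export. A thin CLI
wraps the same pipeline (`sixocellus simulate|label|classify|survey|
export-nexus|tables`).

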