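"""Bilateral reconciliation, species aggregation and survey statistics.

Ocelli are assumed bilaterally symmetric: the same complement is present
on the sinistral and dextral sides of an individual regardless of minor
positional differences.  When the two sides carry different numbers, the
side with fewer ocelli is treated as a subset of the side with more; the
individual's complement is the union of its sides.  Sides that are
mutually non-nested (neither a subset of the other) are *discordant* —
a rare condition — and still contribute their union.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .homology import LabeledSide
from .obsmodel import IDENTITY_ORDER, OcellusIdentity, ValidationError
from .patterns import MEMBER_SETS, PatternCall, PatternName, pattern_of

__all__ = [
    "IndividualSummary",
    "SpeciesSummary",
    "SurveyReport",
    "reconcile_individual",
    "aggregate_species",
    "survey_stats",
]

IdentitySet = frozenset


@dataclass
class IndividualSummary:
    """Reconciled bilateral ocellus complement for one specimen."""

    specimen_id: str
    left_set: Optional[frozenset[OcellusIdentity]]
    right_set: Optional[frozenset[OcellusIdentity]]
    complement: frozenset[OcellusIdentity]
    single_sided: bool
    symmetric: Optional[bool]
    discordant: bool
    patterns: dict[str, PatternCall]
    taxon: tuple[str, str, str] = ("", "", "")

    @property
    def asymmetric(self) -> bool:
        """Different ocellus counts on the two sides (single-sided: False)."""
        if self.single_sided:
            return False
        return len(self.left_set) != len(self.right_set) or self.discordant

    @property
    def sighted(self) -> bool:
        return bool(self.complement)


def reconcile_individual(
    left: Optional[LabeledSide],
    right: Optional[LabeledSide],
    specimen_id: str = "",
    taxon: tuple[str, str, str] = ("", "", ""),
) -> IndividualSummary:
    """Apply the bilateral-symmetry subset rule to one specimen's sides.

    Positional differences alone never break homology: only membership
    of the identity sets matters here.
    """
    if left is None and right is None:
        raise ValidationError("at least one side is required")
    lset = left.identity_set if left is not None else None
    rset = right.identity_set if right is not None else None
    single = lset is None or rset is None
    if single:
        complement = lset if lset is not None else rset
        symmetric: Optional[bool] = None
        discordant = False
    else:
        complement = frozenset(lset | rset)
        symmetric = lset == rset
        discordant = not (lset <= rset or rset <= lset)
    patterns = {"complement": pattern_of(complement)}
    if lset is not None:
        patterns["sinistral"] = pattern_of(lset)
    if rset is not None:
        patterns["dextral"] = pattern_of(rset)
    return IndividualSummary(
        specimen_id=specimen_id,
        left_set=lset,
        right_set=rset,
        complement=frozenset(complement),
        single_sided=single,
        symmetric=symmetric,
        discordant=discordant,
        patterns=patterns,
        taxon=taxon,
    )


@dataclass
class SpeciesSummary:
    """Per-species aggregation over reconciled individuals."""

    taxon: tuple[str, str, str]
    n_individuals: int
    morphs: dict[frozenset[OcellusIdentity], int]
    modal_pattern: PatternName
    polymorphic: bool
    morphs_nested: bool
    presence_freq: dict[OcellusIdentity, float]
    eyespot: str
    eyespot_counts: dict[str, int]

    @property
    def family(self) -> str:
        return self.taxon[0]


def _modal_pattern(calls: list[PatternCall]) -> PatternName:
    """Most frequent defined pattern; ties go to the pattern with more
    ocelli (lesser morphs are read as reductions).  ABNORMAL wins only
    when no call evidences a defined pattern."""
    votes = Counter()
    for call in calls:
        name = call.best_defined_name()
        if name is not None:
            votes[name] += 1
    if not votes:
        return PatternName.ABNORMAL
    top = max(votes.values())
    tied = [name for name, v in votes.items() if v == top]
    return max(tied, key=lambda name: (len(MEMBER_SETS[name]), name.value))


def aggregate_species(
    individuals: list[IndividualSummary],
    eyespots: Optional[Iterable[str]] = None,
) -> SpeciesSummary:
    """Build the species-level morph table and polymorphism flag.

    A species is polymorphic when its individuals' complements span at
    least two distinct ocellus *counts*.  ``morphs_nested`` records
    whether every lesser morph is a subset of every greater one, the
    dominant mode of intraspecific variation.
    """
    if not individuals:
        raise ValidationError("aggregate_species requires at least one individual")
    taxa = {ind.taxon for ind in individuals}
    if len(taxa) > 1:
        raise ValidationError(f"mixed-species input: {sorted(taxa)}")
    (taxon,) = taxa

    morphs = Counter(ind.complement for ind in individuals)
    counts = {len(m) for m in morphs}
    polymorphic = len(counts) >= 2
    nested = True
    morph_list = sorted(morphs, key=len)
    for i, a in enumerate(morph_list):
        for b in morph_list[i + 1:]:
            if len(a) < len(b) and not a <= b:
                nested = False
            if len(a) == len(b) and a != b:
                nested = False

    n = len(individuals)
    presence = {
        ident: sum(1 for ind in individuals if ident in ind.complement) / n
        for ident in IDENTITY_ORDER
    }
    states = Counter(eyespots or [])
    for s in states:
        if s not in {"present", "absent", "unknown"}:
            raise ValidationError(f"unknown eyespot state {s!r}")
    if states.get("present"):
        eyespot = "present"
    elif states.get("absent"):
        eyespot = "absent"
    else:
        eyespot = "unknown"
    modal = _modal_pattern([ind.patterns["complement"] for ind in individuals])
    return SpeciesSummary(
        taxon=taxon,
        n_individuals=n,
        morphs=dict(morphs),
        modal_pattern=modal,
        polymorphic=polymorphic,
        morphs_nested=nested,
        presence_freq=presence,
        eyespot=eyespot,
        eyespot_counts={s: states.get(s, 0) for s in ("present", "absent", "unknown")},
    )


@dataclass
class SurveyReport:
    """Whole-survey tallies.  Fractions are recomputed from counts on
    access; nothing rounded is stored."""

    n_individuals: int
    n_species: int
    n_genera: int
    n_two_sided: int
    n_sighted: int
    asymmetric_count: int
    discordant_count: int
    polymorphic_species_count: int
    per_family_pattern: pd.DataFrame
    eyespot_table: pd.DataFrame

    @property
    def asymmetric_fraction(self) -> float:
        """Asymmetric individuals over all individuals examined."""
        return self.asymmetric_count / self.n_individuals if self.n_individuals else 0.0

    @property
    def asymmetric_fraction_two_sided(self) -> float:
        """Asymmetry is only observable with two sides; this uses the
        two-sided denominator."""
        return self.asymmetric_count / self.n_two_sided if self.n_two_sided else 0.0

    @property
    def asymmetric_fraction_sighted(self) -> float:
        """Denominator restricted to ocellus-bearing individuals (an
        eyeless individual cannot be count-asymmetric)."""
        return self.asymmetric_count / self.n_sighted if self.n_sighted else 0.0

    @property
    def polymorphic_species_fraction(self) -> float:
        return (
            self.polymorphic_species_count / self.n_species if self.n_species else 0.0
        )

    def to_json_dict(self) -> dict:
        return {
            "n_individuals": self.n_individuals,
            "n_species": self.n_species,
            "n_genera": self.n_genera,
            "n_two_sided": self.n_two_sided,
            "n_sighted": self.n_sighted,
            "asymmetric_count": self.asymmetric_count,
            "asymmetric_fraction": self.asymmetric_fraction,
            "asymmetric_fraction_two_sided": self.asymmetric_fraction_two_sided,
            "asymmetric_fraction_sighted": self.asymmetric_fraction_sighted,
            "discordant_count": self.discordant_count,
            "polymorphic_species_count": self.polymorphic_species_count,
            "polymorphic_species_fraction": self.polymorphic_species_fraction,
        }

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_family_pattern.to_csv(out / "pattern_by_family.tsv", sep="\t")
        self.eyespot_table.to_csv(out / "eyespot_by_family.tsv", sep="\t")
        (out / "survey_summary.json").write_text(
            json.dumps(self.to_json_dict(), indent=2) + "\n"
        )


def survey_stats(
    species: list[SpeciesSummary], individuals: list[IndividualSummary]
) -> SurveyReport:
    """Survey-wide asymmetry, polymorphism and distribution tables."""
    if not individuals:
        raise ValidationError("survey_stats requires at least one individual")
    two_sided = [ind for ind in individuals if not ind.single_sided]
    asymmetric = sum(1 for ind in two_sided if ind.asymmetric)
    discordant = sum(1 for ind in two_sided if ind.discordant)
    sighted = sum(1 for ind in individuals if ind.sighted)

    pattern_cells: Counter = Counter()
    for sp in species:
        pattern_cells[(sp.family, sp.modal_pattern.value)] += 1
    families = sorted({f for f, _ in pattern_cells})
    pattern_names = [p.value for p in PatternName]
    per_family = pd.DataFrame(
        [[pattern_cells.get((f, p), 0) for p in pattern_names] for f in families],
        index=pd.Index(families, name="family"),
        columns=pattern_names,
    )

    eyespot_rows = {}
    for sp in species:
        fam = sp.family
        entry = eyespot_rows.setdefault(fam, {"genera": set(), "species": 0})
        if sp.eyespot == "present":
            entry["genera"].add(sp.taxon[1])
            entry["species"] += 1
    eyespot_table = pd.DataFrame(
        [
            {"family": fam, "genera": len(v["genera"]), "species": v["species"]}
            for fam, v in sorted(eyespot_rows.items())
        ]
    ).set_index("family") if eyespot_rows else pd.DataFrame(
        columns=["genera", "species"], index=pd.Index([], name="family")
    )

    return SurveyReport(
        n_individuals=len(individuals),
        n_species=len(species),
        n_genera=len({sp.taxon[1] for sp in species}),
        n_two_sided=len(two_sided),
        n_sighted=sighted,
        asymmetric_count=asymmetric,
        discordant_count=discordant,
        polymorphic_species_count=sum(1 for sp in species if sp.polymorphic),
        per_family_pattern=per_family,
        eyespot_table=eyespot_table,
    )
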