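"""Named lateral-ocellus patterns, the set classifier and the loss lattice.

Eleven defined outcomes exist: the theoretical six-ocellus root, nine
named general patterns with fewer than six ocelli (Types 5, 4A-4C,
3A-3B, 2A-2B, 1) and the eyeless state.  Any other identity combination
-- including any side bearing an accessory ocellus -- is ABNORMAL.  The
named patterns are connected by a derivation lattice whose edges are
single- or multi-ocellus losses.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Optional

from .obsmodel import (
    ACCESSORY_IDENTITIES,
    CORE_IDENTITIES,
    IDENTITY_ORDER,
    OcellusIdentity,
    ValidationError,
)

__all__ = [
    "PatternName",
    "PatternCall",
    "LatticeEdge",
    "MEMBER_SETS",
    "pattern_of",
    "lattice",
    "is_reduction",
    "catalog_size",
    "reduction_children",
    "catalog_json",
]

I = OcellusIdentity


class PatternName(str, enum.Enum):
    SIX = "SIX"
    T5 = "T5"
    T4A = "T4A"
    T4B = "T4B"
    T4C = "T4C"
    T3A = "T3A"
    T3B = "T3B"
    T2A = "T2A"
    T2B = "T2B"
    T1 = "T1"
    ABSENT = "ABSENT"
    ABNORMAL = "ABNORMAL"


def _fs(*ids: OcellusIdentity) -> FrozenSet[OcellusIdentity]:
    return frozenset(ids)


#: Member sets of the eleven defined patterns (ABNORMAL has none).
MEMBER_SETS: dict[PatternName, FrozenSet[OcellusIdentity]] = {
    PatternName.SIX: _fs(I.ALMA, I.MLMA, I.PLMA, I.ADMI, I.PDMI, I.PLMI),
    PatternName.T5: _fs(I.ALMA, I.MLMA, I.PLMA, I.ADMI, I.PDMI),
    PatternName.T4A: _fs(I.ALMA, I.MLMA, I.PLMA, I.ADMI),
    PatternName.T4B: _fs(I.MLMA, I.PLMA, I.PDMI, I.PLMI),
    PatternName.T4C: _fs(I.MLMA, I.PLMA, I.ADMI, I.PDMI),
    PatternName.T3A: _fs(I.MLMA, I.PLMA, I.PDMI),
    PatternName.T3B: _fs(I.MLMA, I.PLMA, I.ADMI),
    PatternName.T2A: _fs(I.MLMA, I.PLMA),
    PatternName.T2B: _fs(I.PLMA, I.PDMI),
    PatternName.T1: _fs(I.PLMA),
    PatternName.ABSENT: _fs(),
}

_SET_TO_NAME = {members: name for name, members in MEMBER_SETS.items()}


@dataclass(frozen=True)
class PatternCall:
    """Outcome of classifying an identity set.

    ``residual`` is the non-accessory part of the input; for ABNORMAL
    calls ``residual_name`` records the named pattern the residual
    matches, if any, so downstream aggregation can still reason about the
    underlying type.
    """

    name: PatternName
    residual: FrozenSet[OcellusIdentity]
    accessory: FrozenSet[OcellusIdentity] = frozenset()
    residual_name: Optional[PatternName] = None
    notes: tuple[str, ...] = ()

    @property
    def count(self) -> int:
        return len(self.residual) + len(self.accessory)

    @property
    def defined(self) -> bool:
        return self.name is not PatternName.ABNORMAL

    def best_defined_name(self) -> Optional[PatternName]:
        """The defined pattern this call evidences, if any."""
        if self.defined:
            return self.name
        return self.residual_name


def pattern_of(identities: Iterable[OcellusIdentity]) -> PatternCall:
    """Classify an identity set into one of the twelve outcomes.

    Total over all 2**10 subsets of the ten identities.  Accessory
    identities are stripped first and always force ABNORMAL; the residual
    non-accessory set is matched exactly against the eleven member sets.
    """
    idset = frozenset(OcellusIdentity(i) for i in identities)
    accessory = frozenset(idset & ACCESSORY_IDENTITIES)
    residual = frozenset(idset - ACCESSORY_IDENTITIES)
    residual_name = _SET_TO_NAME.get(residual)
    notes: list[str] = []
    if accessory:
        notes.append(
            "accessory ocelli present: "
            + ", ".join(i.value for i in IDENTITY_ORDER if i in accessory)
        )
        if residual_name is not None:
            notes.append(f"residual set matches {residual_name.value}")
        return PatternCall(
            name=PatternName.ABNORMAL,
            residual=residual,
            accessory=accessory,
            residual_name=residual_name,
            notes=tuple(notes),
        )
    if residual_name is None:
        notes.append(
            "identity set matches no named pattern: "
            + ("{" + ", ".join(i.value for i in IDENTITY_ORDER if i in residual) + "}")
        )
        return PatternCall(
            name=PatternName.ABNORMAL, residual=residual, notes=tuple(notes)
        )
    return PatternCall(name=residual_name, residual=residual, residual_name=residual_name)


@dataclass(frozen=True)
class LatticeEdge:
    child: PatternName
    parent: PatternName
    lost: FrozenSet[OcellusIdentity]

    def __post_init__(self) -> None:
        if not self.lost:
            raise ValidationError("a lattice edge must lose at least one ocellus")
        if MEMBER_SETS[self.child] != MEMBER_SETS[self.parent] - self.lost:
            raise ValidationError(
                f"edge {self.parent.value}->{self.child.value}: child set is not "
                f"parent minus lost"
            )


_EDGES: tuple[tuple[PatternName, PatternName, tuple[OcellusIdentity, ...]], ...] = (
    (PatternName.T5, PatternName.SIX, (I.PLMI,)),
    (PatternName.T4B, PatternName.SIX, (I.ALMA, I.ADMI)),
    (PatternName.T4A, PatternName.T5, (I.PDMI,)),
    (PatternName.T4C, PatternName.T5, (I.ALMA,)),
    (PatternName.T3A, PatternName.T4C, (I.ADMI,)),
    (PatternName.T3B, PatternName.T4C, (I.PDMI,)),
    (PatternName.T2A, PatternName.T3A, (I.PDMI,)),
    (PatternName.T2A, PatternName.T3B, (I.ADMI,)),
    (PatternName.T2B, PatternName.T3A, (I.MLMA,)),
    (PatternName.T1, PatternName.T2A, (I.MLMA,)),
    (PatternName.T1, PatternName.T2B, (I.PDMI,)),
    (PatternName.ABSENT, PatternName.T1, (I.PLMA,)),
)


def lattice() -> list[LatticeEdge]:
    """The twelve derivation edges connecting the defined patterns."""
    return [LatticeEdge(child=c, parent=p, lost=frozenset(lost)) for c, p, lost in _EDGES]


def is_reduction(p: PatternName, q: PatternName) -> bool:
    """True iff pattern ``p`` is derivable from ``q`` by ocellus loss
    (member-set inclusion; reflexive)."""
    if PatternName.ABNORMAL in (p, q):
        raise ValidationError("ABNORMAL has no place in the reduction order")
    return MEMBER_SETS[p] <= MEMBER_SETS[q]


def catalog_size() -> int:
    """Number of named general patterns with fewer than six ocelli."""
    return len(MEMBER_SETS) - 2  # excludes the SIX root and ABSENT


def reduction_children(name: PatternName) -> list[PatternName]:
    """Defined patterns reachable by removing exactly one ocellus."""
    members = MEMBER_SETS[name]
    out = []
    for ident in IDENTITY_ORDER:
        if ident in members:
            child = _SET_TO_NAME.get(members - {ident})
            if child is not None:
                out.append(child)
    return out


def catalog_json() -> dict:
    """Pattern catalog (member sets + parent edges) as plain data."""
    edges = lattice()
    return {
        name.value: {
            "members": [i.value for i in IDENTITY_ORDER if i in members],
            "parents": [
                {
                    "parent": e.parent.value,
                    "lost": [i.value for i in IDENTITY_ORDER if i in e.lost],
                }
                for e in edges
                if e.child is name
            ],
        }
        for name, members in MEMBER_SETS.items()
    }
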