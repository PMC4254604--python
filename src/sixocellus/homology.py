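"""Assign ocellus identities to one side's observations.

Homology is assigned from *relative* position and size, never absolute
position.  The rules, in composition order:

1.  ``split_size_tiers`` — major ocelli are, with few exceptions, larger
    than minor ocelli; the tier split is placed at the largest
    multiplicative diameter gap exceeding a configurable ratio.
2.  ``assign_major_identities`` — the majors form an anteroposterior row;
    with k majors the posterior-most k of (AALMa, ALMa, MLMa, PLMa) are
    used, which builds the coincidence chain (ALMa implies MLMa implies
    PLMa; AALMa implies ALMa) into the output by construction.
3.  ``assign_minor_identities`` — minors are placed by 45-degree angular
    sector relative to the PLMa anchor (ADMi anterodorsal/dorsal/
    posterodorsal; PDMi dorsal/posterodorsal/posterior; PLMi posterior to
    PLMa and ventral to PDMi; accessory APLMi posteroventral to PDMi,
    numbered by increasing distance).  A lone minor in the dorsal/
    posterodorsal overlap defaults to PDMi — the most prevalent minor —
    and is flagged ``tie_broken``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

from .obsmodel import (
    OcellusIdentity,
    OcellusObservation,
    SideRecord,
    ValidationError,
)

__all__ = [
    "SectorConfig",
    "LabeledSide",
    "FIRM",
    "TIE_BROKEN",
    "SECTOR_NAMES",
    "sector_of",
    "split_size_tiers",
    "assign_major_identities",
    "assign_minor_identities",
    "label_side",
    "pdmi_position_class",
]

I = OcellusIdentity

FIRM = "firm"
TIE_BROKEN = "tie_broken"

#: Sector k spans angles [45k - offset, 45(k+1) - offset) with posterior at
#: 0 degrees and dorsal at +90 degrees in the (ap, dv) plane.
SECTOR_NAMES = (
    "posterior",
    "posterodorsal",
    "dorsal",
    "anterodorsal",
    "anterior",
    "anteroventral",
    "ventral",
    "posteroventral",
)

_MAJOR_ROW = (I.AALMA, I.ALMA, I.MLMA, I.PLMA)

# Sectors (relative to PLMa) in which each in-model minor may lie.
_ADMI_SECTORS = {"anterodorsal", "dorsal", "posterodorsal"}
_PDMI_SECTORS = {"dorsal", "posterodorsal", "posterior"}
_UPPER_SECTORS = _ADMI_SECTORS | _PDMI_SECTORS - {"posterior"}
_LOWER_SECTORS = {"posteroventral", "ventral"}


@dataclass(frozen=True)
class SectorConfig:
    """Geometry and size thresholds for homology assignment.

    All quantities are dimensionless except the angular offset (degrees).
    ``major_minor_ratio`` is the multiplicative diameter gap that
    separates size tiers; ``size_tolerance`` is the band within which two
    normalized diameters count as "similar".  ``p1_dv_tol`` and
    ``p2_dv_max`` band the dorsal offset of PDMi from the major-ocellus
    row into the three classical positions of the fourth buthid ocellus.
    """

    boundary_offset_deg: float = 22.5
    major_minor_ratio: float = 1.5
    size_tolerance: float = 0.1
    p1_dv_tol: float = 0.03
    p2_dv_max: float = 0.10

    def __post_init__(self) -> None:
        if not self.major_minor_ratio > 1.0:
            raise ValidationError("major_minor_ratio must exceed 1")
        if not (0.0 <= self.size_tolerance < 1.0):
            raise ValidationError("size_tolerance must be in [0, 1)")

    @classmethod
    def from_dict(cls, data: dict) -> "SectorConfig":
        known = {k: v for k, v in (data or {}).items() if k in cls.__dataclass_fields__}
        return cls(**known)

    @classmethod
    def from_yaml(cls, path) -> "SectorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data.get("sector", data))


def sector_of(dap: float, ddv: float, cfg: Optional[SectorConfig] = None) -> str:
    """Angular sector of an (ap, dv) offset; posterior = +ap, dorsal = +dv."""
    offset = cfg.boundary_offset_deg if cfg is not None else 22.5
    ang = math.degrees(math.atan2(ddv, dap))
    k = int(math.floor((ang + offset) / 45.0)) % 8
    return SECTOR_NAMES[k]


@dataclass
class LabeledSide:
    """One side's observations with assigned homology identities.

    ``labels`` maps observation index (into ``observations``) to identity
    and is injective; ``confidence`` marks each assignment ``firm`` or
    ``tie_broken``; indices in ``unassigned`` failed every positional
    constraint.  ``flags`` carries abnormality notes.
    """

    side: str
    observations: list[OcellusObservation] = field(default_factory=list)
    labels: dict[int, OcellusIdentity] = field(default_factory=dict)
    confidence: dict[int, str] = field(default_factory=dict)
    unassigned: list[int] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assigned = list(self.labels.values())
        if len(assigned) != len(set(assigned)):
            raise ValidationError("labels must be injective (one observation per identity)")
        members = set(assigned)
        if I.ALMA in members and not {I.MLMA, I.PLMA} <= members:
            raise ValidationError("ALMa implies MLMa and PLMa")
        if I.MLMA in members and I.PLMA not in members:
            raise ValidationError("MLMa implies PLMa")
        if I.AALMA in members and I.ALMA not in members:
            raise ValidationError("AALMa implies ALMa")

    @property
    def identity_set(self) -> frozenset[OcellusIdentity]:
        return frozenset(self.labels.values())

    def identity_of(self, index: int) -> Optional[OcellusIdentity]:
        return self.labels.get(index)

    def tie_broken_indices(self) -> list[int]:
        return [i for i, c in self.confidence.items() if c == TIE_BROKEN]


def split_size_tiers(
    observations: Sequence[OcellusObservation], cfg: SectorConfig
) -> tuple[list[int], list[int], bool]:
    """Split a side's observations into (majors, minors) by diameter.

    Returns index lists (into ``observations``) plus a flag marking a
    tie-broken split.  Majors are mutually similar in size, so the split
    goes at the first multiplicative gap in the descending diameter
    sequence that exceeds ``cfg.major_minor_ratio`` (minor ocelli have
    sizeable gaps among themselves, so a later, even larger gap must not
    capture minors into the major tier), capped at four majors.  With no
    qualifying gap, up to two similar ocelli are all treated as majors
    (the two-major patterns dominate that regime); larger gap-free sides
    are resolved the same way but flagged.
    """
    n = len(observations)
    if n > 10:
        raise ValidationError(f"a side carries at most 10 observations, got {n}")
    if n == 0:
        return [], [], False
    order = sorted(range(n), key=lambda i: -observations[i].diameter)
    diam = [observations[i].diameter for i in order]
    for k in range(1, min(4, n - 1) + 1):
        if diam[k - 1] / diam[k] > cfg.major_minor_ratio:
            return order[:k], order[k:], False
    if n <= 2:
        return order, [], False
    if n <= 4:
        return order, [], True
    return order[:4], order[4:], True


def assign_major_identities(
    majors: Sequence[int],
    observations: Sequence[OcellusObservation],
    cfg: SectorConfig,
) -> tuple[dict[int, OcellusIdentity], list[int], list[str]]:
    """Label the major-tier observations along the anteroposterior row.

    With k <= 4 majors the posterior-most k identities of
    (AALMa, ALMa, MLMa, PLMa) are assigned in ap order; supernumerary
    anterior majors are left unassigned and flagged.
    """
    ordered = sorted(majors, key=lambda i: observations[i].ap)
    flags: list[str] = []
    unassigned: list[int] = []
    if len(ordered) > 4:
        extra = len(ordered) - 4
        flags.append(f"abnormal: {len(ordered)} major-tier ocelli; {extra} left unassigned")
        unassigned = ordered[:extra]
        ordered = ordered[extra:]
    identities = _MAJOR_ROW[len(_MAJOR_ROW) - len(ordered):]
    labels = {idx: ident for idx, ident in zip(ordered, identities)}
    return labels, unassigned, flags


def assign_minor_identities(
    minors: Sequence[int],
    anchor: Optional[int],
    labels: dict[int, OcellusIdentity],
    observations: Sequence[OcellusObservation],
    cfg: SectorConfig,
) -> tuple[dict[int, OcellusIdentity], dict[int, str], list[int], list[str]]:
    """Label minor-tier observations by sector relative to the PLMa anchor.

    Returns (labels, confidence, unassigned, flags) for the minors only.
    """
    out: dict[int, OcellusIdentity] = {}
    conf: dict[int, str] = {}
    unassigned: list[int] = []
    flags: list[str] = []
    if not minors:
        return out, conf, unassigned, flags
    if anchor is None:
        flags.append("abnormal: minor ocelli present with no PLMa anchor")
        return out, conf, list(minors), flags

    ax, ay = observations[anchor].ap, observations[anchor].dv
    sectors = {
        i: sector_of(observations[i].ap - ax, observations[i].dv - ay, cfg) for i in minors
    }
    upper = [i for i in minors if sectors[i] in _UPPER_SECTORS]
    post = [i for i in minors if sectors[i] == "posterior"]
    lower = [i for i in minors if sectors[i] in _LOWER_SECTORS]
    for i in minors:
        if sectors[i] not in _UPPER_SECTORS | {"posterior"} | _LOWER_SECTORS:
            unassigned.append(i)

    admi: Optional[int] = None
    pdmi: Optional[int] = None
    if len(upper) == 1:
        (u,) = upper
        if sectors[u] == "anterodorsal":
            admi = u
            conf[u] = FIRM
        else:
            # dorsal / posterodorsal overlap: PDMi is the most prevalent
            # minor, so a lone minor there defaults to PDMi.
            pdmi = u
            conf[u] = TIE_BROKEN
    elif len(upper) >= 2:
        # ADMi lies anterodorsal/anterior to PDMi: anterior-most is ADMi.
        by_ap = sorted(upper, key=lambda i: observations[i].ap)
        admi, pdmi = by_ap[0], by_ap[-1]
        conf[admi] = FIRM
        conf[pdmi] = FIRM
        for mid in by_ap[1:-1]:
            unassigned.append(mid)
        if len(by_ap) > 2:
            flags.append("abnormal: more than two minors dorsal of PLMa")

    if pdmi is None and post:
        # PDMi may sit directly posterior to PLMa (well separated in
        # dorsoventrally compressed taxa); with two candidates the more
        # dorsal one is PDMi.
        by_dv = sorted(post, key=lambda i: -observations[i].dv)
        pdmi = by_dv[0]
        conf[pdmi] = TIE_BROKEN if len(post) == 1 else FIRM

    if admi is not None:
        out[admi] = I.ADMI
    if pdmi is not None:
        out[pdmi] = I.PDMI

    remaining = [i for i in post + lower if i not in out]
    if remaining:
        if pdmi is None:
            flags.append("abnormal: posterior/ventral minors with no PDMi anchor")
            unassigned.extend(remaining)
        else:
            px, py = observations[pdmi].ap, observations[pdmi].dv
            rel = {
                i: sector_of(observations[i].ap - px, observations[i].dv - py, cfg)
                for i in remaining
            }
            ventral = [i for i in remaining if rel[i] == "ventral"]
            postero = [i for i in remaining if rel[i] == "posteroventral"]
            plmi: Optional[int] = None
            if ventral:
                # PLMi is ventral to PDMi; pick the most nearly directly
                # ventral candidate, surplus joins the accessory pool.
                def _ventralness(i: int) -> float:
                    ang = math.degrees(
                        math.atan2(observations[i].dv - py, observations[i].ap - px)
                    )
                    return abs(ang + 90.0)

                ventral.sort(key=_ventralness)
                plmi = ventral[0]
                out[plmi] = I.PLMI
                conf[plmi] = FIRM
                postero.extend(ventral[1:])
            # Accessory posteroventral minors are numbered by increasing
            # distance from PDMi.
            postero.sort(
                key=lambda i: math.hypot(
                    observations[i].ap - px, observations[i].dv - py
                )
            )
            for ident, i in zip((I.APLMI1, I.APLMI2, I.APLMI3), postero):
                out[i] = ident
                conf[i] = FIRM
            for i in postero[3:]:
                unassigned.append(i)
            if postero[3:]:
                flags.append("abnormal: more than three accessory posteroventral minors")
            for i in remaining:
                if i not in out and i not in unassigned:
                    unassigned.append(i)
    return out, conf, unassigned, flags


def label_side(record: SideRecord, cfg: Optional[SectorConfig] = None) -> LabeledSide:
    """Full homology assignment for one side.

    Composition of tier split, major-row assignment and sector-based
    minor assignment; deterministic for a fixed configuration.
    """
    cfg = cfg or SectorConfig()
    obs = record.observations
    if not obs:
        return LabeledSide(side=record.side, observations=list(obs))

    majors, minors, tier_tb = split_size_tiers(obs, cfg)
    major_labels, major_unassigned, flags = assign_major_identities(majors, obs, cfg)
    confidence = {i: (TIE_BROKEN if tier_tb else FIRM) for i in major_labels}

    anchor = next((i for i, ident in major_labels.items() if ident is I.PLMA), None)
    minor_labels, minor_conf, minor_unassigned, minor_flags = assign_minor_identities(
        minors, anchor, major_labels, obs, cfg
    )
    labels = {**major_labels, **minor_labels}
    confidence.update(minor_conf)
    flags = flags + minor_flags
    unassigned = sorted(set(major_unassigned) | set(minor_unassigned))
    if tier_tb:
        flags.append("tie_broken: no clear major/minor diameter gap")
    return LabeledSide(
        side=record.side,
        observations=list(obs),
        labels=labels,
        confidence=confidence,
        unassigned=unassigned,
        flags=flags,
    )


def pdmi_position_class(labeled: LabeledSide, cfg: Optional[SectorConfig] = None) -> str:
    """Band PDMi's dorsal offset from the three-major row into P1/P2/P3.

    P1: in the plane of the first three lateral ocelli; P2: moderately
    dorsal (on the carapace ridge); P3: well above it.  Requires PDMi and
    the full ALMa-MLMa-PLMa row, else ``not_applicable``.
    """
    cfg = cfg or SectorConfig()
    by_identity = {ident: i for i, ident in labeled.labels.items()}
    needed = (I.ALMA, I.MLMA, I.PLMA, I.PDMI)
    if any(ident not in by_identity for ident in needed):
        return "not_applicable"
    xs = [labeled.observations[by_identity[i]].ap for i in (I.ALMA, I.MLMA, I.PLMA)]
    ys = [labeled.observations[by_identity[i]].dv for i in (I.ALMA, I.MLMA, I.PLMA)]
    # Least-squares row axis through the three majors.
    n = 3
    mx, my = sum(xs) / n, sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    slope = sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / sxx if sxx > 0 else 0.0
    p = labeled.observations[by_identity[I.PDMI]]
    offset = p.dv - (my + slope * (p.ap - mx))
    if offset > cfg.p2_dv_max:
        return "P3"
    if offset > cfg.p1_dv_tol:
        return "P2"
    return "P1"
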