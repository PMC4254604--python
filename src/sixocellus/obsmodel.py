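"""Domain types, observation-table I/O and survey fixture tables.

The unit of observation is a single lateral ocellus seen on one side of a
scorpion carapace.  Positions live in a dimensionless per-side frame with
``ap`` increasing anterior -> posterior and ``dv`` increasing ventral ->
dorsal; diameters are relative to the largest ocellus on the same side.
Dextral (right-hand) sides are mirrored into this frame on ingest so that
all downstream geometry is side-agnostic.

Eyespots -- lensless photosensitive spots ventral/posteroventral to the
lateral ocelli -- are *not* ocelli.  They are carried as side-level
tri-state evidence (``present`` / ``absent`` / ``unknown``), never as an
observation with an ocellus identity.
"""

from __future__ import annotations

import enum
import io
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

__all__ = [
    "OcellusIdentity",
    "OcellusObservation",
    "SideRecord",
    "IndividualRecord",
    "FixtureTable",
    "FormatError",
    "ValidationError",
    "IntegrityError",
    "IDENTITY_ORDER",
    "MAJOR_IDENTITIES",
    "MINOR_IDENTITIES",
    "ACCESSORY_IDENTITIES",
    "CORE_IDENTITIES",
    "SIDES",
    "EYESPOT_STATES",
    "OBSERVATION_COLUMNS",
    "read_observations",
    "write_observations",
    "records_from_frame",
    "records_to_frame",
    "load_fixture",
    "tabulate_eyelessness",
    "tabulate_survey_totals",
    "tabulate_eyespot_records",
]


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(ValueError):
    """Row- or value-level content violates a domain invariant."""


class IntegrityError(ValueError):
    """A cross-check against a table's own printed totals failed."""


class OcellusIdentity(str, enum.Enum):
    """The ten homologous lateral-ocellus identities.

    Six identities form the core model: three major ocelli arranged in an
    anteroposterior row (ALMa, MLMa, PLMa) and three minor satellites
    (ADMi, PDMi, PLMi).  Four further identities (AALMa, APLMi1-3) are
    rarely observed accessory ocelli outside the core complement.
    """

    AALMA = "AALMa"
    ALMA = "ALMa"
    MLMA = "MLMa"
    PLMA = "PLMa"
    ADMI = "ADMi"
    PDMI = "PDMi"
    PLMI = "PLMi"
    APLMI1 = "APLMi1"
    APLMI2 = "APLMi2"
    APLMI3 = "APLMi3"

    @property
    def tier(self) -> str:
        return "major" if self in MAJOR_IDENTITIES else "minor"

    @property
    def accessory(self) -> bool:
        return self in ACCESSORY_IDENTITIES


#: Canonical character/reporting order.
IDENTITY_ORDER = (
    OcellusIdentity.AALMA,
    OcellusIdentity.ALMA,
    OcellusIdentity.MLMA,
    OcellusIdentity.PLMA,
    OcellusIdentity.ADMI,
    OcellusIdentity.PDMI,
    OcellusIdentity.PLMI,
    OcellusIdentity.APLMI1,
    OcellusIdentity.APLMI2,
    OcellusIdentity.APLMI3,
)

MAJOR_IDENTITIES = frozenset(
    {OcellusIdentity.AALMA, OcellusIdentity.ALMA, OcellusIdentity.MLMA, OcellusIdentity.PLMA}
)
ACCESSORY_IDENTITIES = frozenset(
    {OcellusIdentity.AALMA, OcellusIdentity.APLMI1, OcellusIdentity.APLMI2, OcellusIdentity.APLMI3}
)
MINOR_IDENTITIES = frozenset(IDENTITY_ORDER) - MAJOR_IDENTITIES
#: The six-ocellus model set (non-accessory identities).
CORE_IDENTITIES = frozenset(IDENTITY_ORDER) - ACCESSORY_IDENTITIES

SIDES = ("sinistral", "dextral")
EYESPOT_STATES = ("present", "absent", "unknown")

OBSERVATION_COLUMNS = [
    "specimen_id",
    "family",
    "subfamily",
    "genus",
    "species",
    "life_stage",
    "side",
    "ap",
    "dv",
    "diameter",
    "lens_present",
    "eyespot_state",
]


@dataclass(frozen=True)
class OcellusObservation:
    """One ocellus on one side: position and relative diameter.

    ``lens_present`` is always true for a real ocellus; lensless rows in
    an observation table are eyespot evidence and never become
    observations.
    """

    ap: float
    dv: float
    diameter: float
    lens_present: bool = True

    def __post_init__(self) -> None:
        if not (self.diameter > 0.0 and self.diameter <= 1.0):
            raise ValidationError(
                f"relative diameter must be in (0, 1], got {self.diameter!r}"
            )


@dataclass
class SideRecord:
    side: str
    observations: list[OcellusObservation] = field(default_factory=list)
    eyespot: str = "unknown"

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValidationError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.eyespot not in EYESPOT_STATES:
            raise ValidationError(
                f"eyespot must be one of {EYESPOT_STATES}, got {self.eyespot!r}"
            )
        if len(self.observations) > 10:
            raise ValidationError("a side carries at most 10 ocellus observations")


@dataclass
class IndividualRecord:
    """One specimen: taxon bookkeeping plus one or two sides."""

    specimen_id: str
    family: str = ""
    subfamily: str = ""
    genus: str = ""
    species: str = ""
    life_stage: str = ""
    sides: dict[str, SideRecord] = field(default_factory=dict)

    @property
    def taxon(self) -> tuple[str, str, str]:
        return (self.family, self.genus, self.species)

    def side(self, which: str) -> Optional[SideRecord]:
        return self.sides.get(which)


@dataclass
class FixtureTable:
    """A verbatim transcription of one of the printed survey tables."""

    table_id: str
    rows: list[dict[str, str]]

    def __post_init__(self) -> None:
        if self.table_id not in {"T1", "T3", "T5"}:
            raise ValidationError(f"unknown table_id {self.table_id!r}")


# ---------------------------------------------------------------------------
# observation-table I/O


def _mirror_ap(ap: float) -> float:
    # Dextral sides are digitised in a right-handed view; reflect about the
    # frame midline.  Rounding keeps mirror(mirror(x)) == x for tabulated
    # precision.
    return round(1.0 - ap, 9)


_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _parse_bool(value: str, row_no: int) -> bool:
    v = str(value).strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValidationError(f"row {row_no}: lens_present must be boolean, got {value!r}")


def records_from_frame(df: pd.DataFrame) -> list[IndividualRecord]:
    """Build :class:`IndividualRecord` objects from an observation frame.

    Rows must follow :data:`OBSERVATION_COLUMNS`.  Row order within a
    (specimen, side) group is preserved as the observation order.
    """
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    records: dict[str, IndividualRecord] = {}
    seen_keys: dict[tuple, int] = {}
    duplicates: list[str] = []

    for pos, row in enumerate(df.itertuples(index=False), start=1):
        specimen = str(row.specimen_id)
        side_name = str(row.side)
        if side_name not in SIDES:
            raise ValidationError(f"row {pos}: unknown side {side_name!r}")
        eyespot = str(row.eyespot_state).strip() if not _isna(row.eyespot_state) else "unknown"
        if eyespot == "" :
            eyespot = "unknown"
        if eyespot not in EYESPOT_STATES:
            raise ValidationError(f"row {pos}: unknown eyespot state {eyespot!r}")
        lens = _parse_bool(row.lens_present, pos)

        rec = records.get(specimen)
        if rec is None:
            rec = IndividualRecord(
                specimen_id=specimen,
                family=_text(row.family),
                subfamily=_text(row.subfamily),
                genus=_text(row.genus),
                species=_text(row.species),
                life_stage=_text(row.life_stage),
            )
            records[specimen] = rec
        side = rec.sides.get(side_name)
        if side is None:
            side = SideRecord(side=side_name, eyespot="unknown")
            rec.sides[side_name] = side

        _merge_eyespot(side, eyespot)

        if not lens:
            # Eyespot evidence / side marker row, never an ocellus.
            continue

        ap = float(row.ap)
        dv = float(row.dv)
        diameter = float(row.diameter)
        if not diameter > 0.0:
            raise ValidationError(f"row {pos}: diameter must be > 0, got {diameter}")
        if side_name == "dextral":
            ap = _mirror_ap(ap)
        key = (specimen, side_name, ap, dv)
        if key in seen_keys:
            duplicates.append(
                f"rows {seen_keys[key]} and {pos}: duplicate observation "
                f"({specimen}, {side_name}, ap={ap}, dv={dv})"
            )
        else:
            seen_keys[key] = pos
        side.observations.append(OcellusObservation(ap=ap, dv=dv, diameter=diameter))

    if duplicates:
        raise ValidationError("duplicate observations: " + "; ".join(duplicates))
    return list(records.values())


def _isna(value) -> bool:
    try:
        return bool(pd.isna(value))
    except (TypeError, ValueError):
        return False


def _text(value) -> str:
    return "" if _isna(value) else str(value)


def _merge_eyespot(side: SideRecord, state: str) -> None:
    # present > absent > unknown: any positive record settles the state.
    rank = {"unknown": 0, "absent": 1, "present": 2}
    if rank[state] > rank[side.eyespot]:
        side.eyespot = state


def read_observations(path: Union[str, Path], format: str = "tsv") -> list[IndividualRecord]:
    """Read a per-specimen ocellus observation table.

    Lines starting ``#`` are treated as provenance comments.  Rows with
    ``lens_present`` false are routed to eyespot evidence.  Dextral sides
    are mirrored into the shared frame.
    """
    if format != "tsv":
        raise FormatError(f"unsupported observation format {format!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return records_from_frame(df)


def records_to_frame(records: Iterable[IndividualRecord]) -> pd.DataFrame:
    """Serialise records to the observation-table schema (inverse mirror applied)."""
    rows = []
    for rec in records:
        for side_name in SIDES:
            side = rec.sides.get(side_name)
            if side is None:
                continue
            for obs in side.observations:
                ap = _mirror_ap(obs.ap) if side_name == "dextral" else obs.ap
                rows.append(
                    {
                        "specimen_id": rec.specimen_id,
                        "family": rec.family,
                        "subfamily": rec.subfamily,
                        "genus": rec.genus,
                        "species": rec.species,
                        "life_stage": rec.life_stage,
                        "side": side_name,
                        "ap": ap,
                        "dv": obs.dv,
                        "diameter": obs.diameter,
                        "lens_present": True,
                        "eyespot_state": side.eyespot,
                    }
                )
            # One marker row per side keeps eyeless sides and eyespot
            # evidence representable.
            rows.append(
                {
                    "specimen_id": rec.specimen_id,
                    "family": rec.family,
                    "subfamily": rec.subfamily,
                    "genus": rec.genus,
                    "species": rec.species,
                    "life_stage": rec.life_stage,
                    "side": side_name,
                    "ap": "",
                    "dv": "",
                    "diameter": "",
                    "lens_present": False,
                    "eyespot_state": side.eyespot,
                }
            )
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)


def write_observations(
    records: Iterable[IndividualRecord],
    path: Union[str, Path],
    header_comment: Optional[str] = None,
) -> None:
    df = records_to_frame(records)
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# fixture tables


_FIXTURE_FILES = {"T1": "table1.tsv", "T3": "table3.tsv", "T5": "table5.tsv"}


def load_fixture(table_id: str) -> FixtureTable:
    """Load one of the packaged survey-table transcriptions (T1, T3, T5)."""
    if table_id not in _FIXTURE_FILES:
        raise ValidationError(f"unknown fixture table {table_id!r}")
    ref = resources.files("sixocellus.data").joinpath(_FIXTURE_FILES[table_id])
    df = pd.read_csv(io.StringIO(ref.read_text()), sep="\t", dtype=str)
    rows = [{k: _text(v) for k, v in row.items()} for row in df.to_dict("records")]
    return FixtureTable(table_id=table_id, rows=rows)


_EYE_STATES = {"abs.", "pres.", "abs./pres."}


def tabulate_eyelessness(t1: FixtureTable) -> tuple[int, int]:
    """Count species lacking median / lateral ocelli in the eyelessness table.

    A species counts as lacking an eye when absence was recorded in at
    least some individuals (state ``abs.`` or the polymorphic
    ``abs./pres.``); a strict ``pres.`` never counts.
    """
    if t1.table_id != "T1":
        raise ValidationError(f"expected table T1, got {t1.table_id}")
    median_absent = 0
    lateral_absent = 0
    for i, row in enumerate(t1.rows, start=1):
        for col in ("median", "lateral"):
            state = row.get(col, "")
            if state not in _EYE_STATES:
                raise ValidationError(f"T1 row {i}: unknown state {state!r} in {col!r}")
        if row["median"] in {"abs.", "abs./pres."}:
            median_absent += 1
        if row["lateral"] in {"abs.", "abs./pres."}:
            lateral_absent += 1
    return median_absent, lateral_absent


def _int_cell(value: str, table: str, row_no: int, col: str) -> int:
    try:
        out = int(str(value).strip())
    except (TypeError, ValueError):
        raise ValidationError(f"{table} row {row_no}: non-integer {col!r} cell {value!r}")
    return out


def tabulate_survey_totals(t3: FixtureTable) -> tuple[int, int, int]:
    """Column sums (genera, species, individuals) over family rows of the
    sampling table, cross-checked against its printed Total row."""
    if t3.table_id != "T3":
        raise ValidationError(f"expected table T3, got {t3.table_id}")
    sums = {"genera": 0, "species": 0, "individuals": 0}
    printed: Optional[dict[str, int]] = None
    for i, row in enumerate(t3.rows, start=1):
        values = {c: _int_cell(row[c], "T3", i, c) for c in sums}
        if row.get("family", "").strip().lower() == "total":
            printed = values
            continue
        for c in sums:
            sums[c] += values[c]
    if printed is not None:
        for c in sums:
            if sums[c] != printed[c]:
                raise IntegrityError(
                    f"T3 column {c!r}: family rows sum to {sums[c]} "
                    f"but the printed total is {printed[c]}"
                )
    return sums["genera"], sums["species"], sums["individuals"]


def tabulate_eyespot_records(t5: FixtureTable) -> tuple[int, int]:
    """(genera, species) with an eyespot record, from the eyespot table."""
    if t5.table_id != "T5":
        raise ValidationError(f"expected table T5, got {t5.table_id}")
    genera = 0
    species = 0
    printed_total: Optional[int] = None
    for i, row in enumerate(t5.rows, start=1):
        count = _int_cell(row["exemplar_species"], "T5", i, "exemplar_species")
        if row.get("genus", "").strip().lower() == "total":
            printed_total = count
            continue
        genera += 1
        species += count
    if printed_total is not None and species != printed_total:
        raise IntegrityError(
            f"T5 exemplar-species column sums to {species} "
            f"but the printed total is {printed_total}"
        )
    return genera, species
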