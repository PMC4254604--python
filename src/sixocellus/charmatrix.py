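"""Species-level character matrices for phylogenetic inference.

Eleven binary characters are coded per species: presence/absence of each
of the ten ocellus identities (identity-level coding is more informative
than raw counts, which can conceal different combinations of the same
number of units) plus the eyespot.  Cells are ``0``, ``1``, polymorphic
``{0,1}`` or missing ``?``; an eyespot recorded ``unknown`` maps to
missing, never to absent.  Writers target NEXUS (PAUP*/MrBayes-style
standard-datatype DATA block) and TNT ``xread``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

from .obsmodel import IDENTITY_ORDER, ValidationError
from .reconcile import SpeciesSummary

__all__ = [
    "CHARACTER_ORDER",
    "CELL_TOKENS",
    "CharacterMatrix",
    "build_matrix",
    "write_nexus",
    "read_nexus",
    "write_tnt",
]

#: Stable character order: the ten identities in canonical order, then the eyespot.
CHARACTER_ORDER = tuple(i.value for i in IDENTITY_ORDER) + ("eyespot",)

#: Canonical cell tokens: absent, present, polymorphic {0,1}, missing.
CELL_TOKENS = ("0", "1", "01", "?")


@dataclass
class CharacterMatrix:
    """Rectangular taxa x characters matrix of discrete cells."""

    taxa: list[str]
    characters: list[str]
    cells: list[list[str]]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(set(self.taxa)):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValidationError(f"duplicate taxon names: {', '.join(dupes)}")
        ncol = len(self.characters)
        for taxon, row in zip(self.taxa, self.cells):
            if len(row) != ncol:
                raise ValidationError(
                    f"ragged matrix: taxon {taxon!r} has {len(row)} cells, expected {ncol}"
                )
            for cell in row:
                if cell not in CELL_TOKENS:
                    raise ValidationError(f"unknown cell token {cell!r} for {taxon!r}")

    @property
    def ntax(self) -> int:
        return len(self.taxa)

    @property
    def nchar(self) -> int:
        return len(self.characters)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.characters == other.characters
            and self.cells == other.cells
        )


def _taxon_label(summary: SpeciesSummary) -> str:
    genus, species = summary.taxon[1], summary.taxon[2]
    label = f"{genus}_{species}".strip("_") or "unnamed_taxon"
    return re.sub(r"\s+", "_", label)


def _freq_cell(freq: float) -> str:
    if freq <= 0.0:
        return "0"
    if freq >= 1.0:
        return "1"
    return "01"


_EYESPOT_CELL = {"present": "1", "absent": "0", "unknown": "?"}


def build_matrix(species: Sequence[SpeciesSummary]) -> CharacterMatrix:
    """Code species summaries into the 11-character matrix.

    An ocellus character is 1 when every individual carries it, 0 when
    none does, polymorphic in between.  All-absent characters are
    retained so that character indices are stable across exports.
    """
    if not species:
        raise ValidationError("build_matrix requires a nonempty species list")
    taxa = [_taxon_label(sp) for sp in species]
    cells = []
    for sp in species:
        row = [_freq_cell(sp.presence_freq[ident]) for ident in IDENTITY_ORDER]
        row.append(_EYESPOT_CELL[sp.eyespot])
        cells.append(row)
    return CharacterMatrix(taxa=taxa, characters=list(CHARACTER_ORDER), cells=cells)


def _nexus_cell(cell: str) -> str:
    return "{01}" if cell == "01" else cell


def write_nexus(matrix: CharacterMatrix, path: Union[str, Path]) -> Path:
    """Write a standard-datatype NEXUS DATA block (round-trips through
    :func:`read_nexus`)."""
    path = Path(path)
    width = max(len(t) for t in matrix.taxa) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={matrix.ntax} NCHAR={matrix.nchar};",
        '    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;',
        "    MATRIX",
    ]
    lines.append(
        "        [ characters: " + " ".join(matrix.characters) + " ]"
    )
    for taxon, row in zip(matrix.taxa, matrix.cells):
        lines.append(f"        {taxon:<{width}}" + "".join(_nexus_cell(c) for c in row))
    lines += ["    ;", "END;", ""]
    path.write_text("\n".join(lines))
    return path


_ROW_RE = re.compile(r"^(\S+)\s+(\S+)$")


def _parse_states(chunk: str, taxon: str) -> list[str]:
    cells: list[str] = []
    i = 0
    while i < len(chunk):
        ch = chunk[i]
        if ch == "{" or ch == "(":
            close = "}" if ch == "{" else ")"
            j = chunk.index(close, i)
            cells.append("".join(sorted(chunk[i + 1: j])))
            i = j + 1
        else:
            cells.append(ch)
            i += 1
    for c in cells:
        if c not in CELL_TOKENS:
            raise ValidationError(f"unknown state token {c!r} in row for {taxon!r}")
    return cells


def read_nexus(path: Union[str, Path]) -> CharacterMatrix:
    """Parse a NEXUS standard DATA block written by :func:`write_nexus`."""
    text = Path(path).read_text()
    char_match = re.search(r"\[\s*characters:\s*([^\]]+)\]", text)
    mat_match = re.search(r"MATRIX(.*?);", text, flags=re.S | re.I)
    if mat_match is None:
        raise ValidationError("no MATRIX block found")
    characters = char_match.group(1).split() if char_match else []
    taxa: list[str] = []
    cells: list[list[str]] = []
    for raw in mat_match.group(1).splitlines():
        line = re.sub(r"\[[^\]]*\]", "", raw).strip()
        if not line:
            continue
        m = _ROW_RE.match(line)
        if m is None:
            raise ValidationError(f"unparseable matrix row: {raw!r}")
        taxa.append(m.group(1))
        cells.append(_parse_states(m.group(2), m.group(1)))
    if not characters:
        characters = [f"char_{i + 1}" for i in range(len(cells[0]) if cells else 0)]
    return CharacterMatrix(taxa=taxa, characters=characters, cells=cells)


def write_tnt(matrix: CharacterMatrix, path: Union[str, Path]) -> Path:
    """Write the same cell model as TNT ``xread`` (polymorphism in
    square brackets, missing ``?``)."""
    path = Path(path)
    width = max(len(t) for t in matrix.taxa) + 2
    lines = [
        "xread",
        "'lateral ocellus and eyespot presence characters'",
        f"{matrix.nchar} {matrix.ntax}",
    ]
    for taxon, row in zip(matrix.taxa, matrix.cells):
        states = "".join("[01]" if c == "01" else c for c in row)
        lines.append(f"{taxon:<{width}}{states}")
    lines += [";", "proc /;", ""]
    path.write_text("\n".join(lines))
    return path
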