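"""Reading and writing crystallographic information files (CIF 1.1).

Parsing is delegated to gemmi's CIF reader (comments, quoted strings,
semicolon text fields and ``0.123(4)`` uncertainty suffixes are all handled
there); this module extracts the minimal content the pipeline needs — cell,
symmetry-operator strings and asymmetric-unit atom sites — and validates it.

Only the first data block that carries both a cell and an atom-site loop is
used; additional blocks are logged and skipped. Sites with occupancy below
0.5 are dropped and the remaining partial occupancies treated as full, which
yields one self-consistent structural model per file.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .elements import is_known, normalize_symbol
from .errors import CifParseError, InvalidCellError, NoAtomsError, NoCellError

logger = logging.getLogger("cif2print")

OCCUPANCY_CUTOFF = 0.5

# both the old and the current CIF dialect for symmetry operator loops
SYMOP_TAGS = ("_symmetry_equiv_pos_as_xyz", "_space_group_symop_operation_xyz")


@dataclass(frozen=True)
class CrystalCell:
    """Unit-cell parameters: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise InvalidCellError(f"cell lengths must be positive: {self}")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise InvalidCellError(f"cell angle {name}={ang} outside (0, 180)")
        if self.volume <= 0:
            raise InvalidCellError(f"degenerate cell (volume <= 0): {self}")

    @property
    def volume(self) -> float:
        """Triclinic cell volume in Å³."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return 0.0
        return self.a * self.b * self.c * math.sqrt(arg)


@dataclass(frozen=True)
class AtomSite:
    """One asymmetric-unit atom: label, element symbol, fractional position."""

    label: str
    element: str
    frac: tuple[float, float, float]
    occupancy: float = 1.0


@dataclass
class StructureRecord:
    """One CIF data block: cell, symmetry-operator strings, atom sites."""

    cell: CrystalCell
    symop_strings: list[str]
    sites: list[AtomSite]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.symop_strings:
            self.symop_strings = ["x,y,z"]
        if not self.sites:
            raise NoAtomsError(f"structure {self.name!r} has no atom sites")


_CELL_TAGS = (
    "_cell_length_a",
    "_cell_length_b",
    "_cell_length_c",
    "_cell_angle_alpha",
    "_cell_angle_beta",
    "_cell_angle_gamma",
)


def _block_cell(block: gemmi.cif.Block) -> CrystalCell | None:
    vals = []
    for tag in _CELL_TAGS:
        raw = block.find_value(tag)
        if raw is None:
            return None
        num = gemmi.cif.as_number(raw)
        if math.isnan(num):
            return None
        vals.append(num)
    return CrystalCell(*vals)


def _block_symops(block: gemmi.cif.Block) -> list[str]:
    for tag in SYMOP_TAGS:
        col = block.find_loop(tag)
        ops = [gemmi.cif.as_string(v).strip() for v in col]
        ops = [o for o in ops if o]
        if ops:
            return ops
        # operator given as a plain key-value pair (P1 files sometimes do this)
        raw = block.find_value(tag)
        if raw is not None:
            op = gemmi.cif.as_string(raw).strip()
            if op:
                return [op]
    return ["x,y,z"]


def _site_element(label: str, type_symbol: str | None) -> str:
    if type_symbol:
        sym = normalize_symbol(type_symbol)
        if sym and is_known(sym):
            return sym
    sym = normalize_symbol(label)
    return sym


def _block_sites(block: gemmi.cif.Block) -> list[AtomSite]:
    table = block.find(
        "_atom_site_",
        ["label", "?type_symbol", "fract_x", "fract_y", "fract_z", "?occupancy"],
    )
    sites: list[AtomSite] = []
    for row in table:
        label = gemmi.cif.as_string(row[0])
        type_symbol = gemmi.cif.as_string(row[1]) if row.has(1) else None
        frac = tuple(gemmi.cif.as_number(row[i]) for i in (2, 3, 4))
        if any(math.isnan(x) for x in frac):
            raise CifParseError(f"non-numeric fractional coordinate for site {label!r}")
        occ = gemmi.cif.as_number(row[5]) if row.has(5) else 1.0
        if math.isnan(occ):
            occ = 1.0
        element = _site_element(label, type_symbol)
        if not element:
            raise CifParseError(f"cannot resolve element for site {label!r}")
        if occ < OCCUPANCY_CUTOFF:
            logger.info("dropping site %s (occupancy %.3f < %.1f)", label, occ, OCCUPANCY_CUTOFF)
            continue
        sites.append(AtomSite(label=label, element=element, frac=frac, occupancy=1.0))
    return sites


def read_cif(source: str | os.PathLike) -> StructureRecord:
    """Parse CIF text or a CIF file into a :class:`StructureRecord`.

    ``source`` may be a path or raw CIF text. The first data block holding
    both cell parameters and an atom-site loop wins; others are skipped with
    a log line. An identity operator is injected when no symmetry loop is
    present. Loop columns are matched by tag name, never by position.
    """
    if isinstance(source, os.PathLike) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        doc = gemmi.cif.read_file(os.fspath(source))
        origin = os.fspath(source)
    else:
        doc = gemmi.cif.read_string(str(source))
        origin = "<text>"

    saw_cell = False
    for block in doc:
        cell = _block_cell(block)
        if cell is None:
            logger.info("block %r in %s: no complete cell, skipping", block.name, origin)
            continue
        saw_cell = True
        sites = _block_sites(block)
        if not sites:
            logger.info("block %r in %s: no atom sites, skipping", block.name, origin)
            continue
        record = StructureRecord(
            cell=cell, symop_strings=_block_symops(block), sites=sites, name=block.name
        )
        return record

    if saw_cell:
        raise NoAtomsError(f"{origin}: no atoms (no data block carries an atom-site loop)")
    raise NoCellError(f"{origin}: no cell (no data block carries complete cell parameters)")


def write_cif(record: StructureRecord) -> str:
    """Serialize a record back to CIF 1.1 text (used by fixtures and tests)."""
    lines = [f"data_{record.name or 'structure'}"]
    cell = record.cell
    for tag, val in zip(_CELL_TAGS, (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)):
        lines.append(f"{tag} {val:.6f}")
    lines.append("loop_")
    lines.append("_symmetry_equiv_pos_as_xyz")
    for op in record.symop_strings:
        lines.append(f"'{op}'")
    lines.append("loop_")
    lines.append("_atom_site_label")
    lines.append("_atom_site_type_symbol")
    lines.append("_atom_site_fract_x")
    lines.append("_atom_site_fract_y")
    lines.append("_atom_site_fract_z")
    lines.append("_atom_site_occupancy")
    for s in record.sites:
        x, y, z = s.frac
        lines.append(f"{s.label} {s.element} {x:.6f} {y:.6f} {z:.6f} {s.occupancy:.4f}")
    return "\n".join(lines) + "\n"
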