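"""Element properties: radii and display colors.

Covalent (Cordero-style single-bond) and van-der-Waals radii are taken from
gemmi's element tables. Elements without a tabulated value fall back to
conservative defaults (1.5 Å covalent, 1.7 Å vdW) with a logged warning, so
exotic or dummy atoms never abort a batch run.
"""

from __future__ import annotations

import logging
import re

import gemmi

logger = logging.getLogger("cif2print")

FALLBACK_COVALENT_R = 1.5
FALLBACK_VDW_R = 1.7

# CPK-style display colors (RGB 0-255), the palette most molecular viewers use.
CPK_COLORS: dict[str, tuple[int, int, int]] = {
    "H": (255, 255, 255),
    "He": (217, 255, 255),
    "Li": (204, 128, 255),
    "Be": (194, 255, 0),
    "B": (255, 181, 181),
    "C": (144, 144, 144),
    "N": (48, 80, 248),
    "O": (255, 13, 13),
    "F": (144, 224, 80),
    "Ne": (179, 227, 245),
    "Na": (171, 92, 242),
    "Mg": (138, 255, 0),
    "Al": (191, 166, 166),
    "Si": (240, 200, 160),
    "P": (255, 128, 0),
    "S": (255, 255, 48),
    "Cl": (31, 240, 31),
    "Ar": (128, 209, 227),
    "K": (143, 64, 212),
    "Ca": (61, 255, 0),
    "Ti": (191, 194, 199),
    "Cr": (138, 153, 199),
    "Mn": (156, 122, 199),
    "Fe": (224, 102, 51),
    "Co": (240, 144, 160),
    "Ni": (80, 208, 80),
    "Cu": (200, 128, 51),
    "Zn": (125, 128, 176),
    "Br": (166, 41, 41),
    "I": (148, 0, 148),
    "Pb": (87, 89, 97),
}
UNKNOWN_COLOR = (255, 20, 147)

_SYMBOL_RE = re.compile(r"[A-Za-z]+")


def normalize_symbol(raw: str) -> str:
    """Strip charge/oxidation suffixes and normalize case ("Pb2+" -> "Pb").

    The leading alphabetic run is kept and capitalized the standard way; a
    two-letter candidate that is not a known element degrades to its first
    letter when that is one ("Cd" stays, "Ca" in a label like "CA1" stays
    calcium — label-based element guessing is the caller's concern).
    """
    m = _SYMBOL_RE.match(raw.strip())
    if not m:
        return ""
    letters = m.group(0)
    sym = letters[:2].capitalize()
    if len(sym) == 2 and not is_known(sym):
        sym = sym[0].upper()
    return sym


def is_known(symbol: str) -> bool:
    el = gemmi.Element(symbol)
    return el.atomic_number > 0


def covalent_radius(symbol: str) -> float:
    """Single-bond covalent radius in Å, with a logged 1.5 Å fallback."""
    el = gemmi.Element(symbol)
    if el.atomic_number == 0:
        logger.warning("no covalent radius for %r; using %.2f Å", symbol, FALLBACK_COVALENT_R)
        return FALLBACK_COVALENT_R
    return float(el.covalent_r)


def vdw_radius(symbol: str) -> float:
    """van-der-Waals radius in Å, with a logged 1.7 Å fallback."""
    el = gemmi.Element(symbol)
    if el.atomic_number == 0:
        logger.warning("no vdW radius for %r; using %.2f Å", symbol, FALLBACK_VDW_R)
        return FALLBACK_VDW_R
    return float(el.vdw_r)


def cpk_color(symbol: str) -> tuple[int, int, int]:
    return CPK_COLORS.get(symbol, UNKNOWN_COLOR)
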