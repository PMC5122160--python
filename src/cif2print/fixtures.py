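"""Synthetic CIF generators with known ground truth.

Four structure archetypes cover the behaviors the pipeline must get right,
without any database download:

``p1_molecule``
    an isolated water molecule in a 15 Å cubic P1 cell — the minimal
    molecular case (one fragment, no symmetry images).
``cocrystal``
    a triclinic-style P-1 co-crystal: a 10-atom carbon sheet ("molecule of
    interest"), two bent 3-atom solvents and a single-atom chloride
    counterion, all on general positions, so inversion doubles every
    fragment. With ``large_counterion=True`` the chloride becomes a 12-atom
    carbocycle that outnumbers the molecule of interest — reproducing the
    documented mis-selection mode of size-based fragment picking.
``rocksalt``
    NaCl with the explicit face-centering operator list in a 5.64 Å cubic
    cell — the extended-solid case that must be packed, where the whole
    packed network is one fragment.
``enantiomer_pair``
    one 5-atom chiral fragment whose P-1 inversion image is its mirror
    enantiomer — the racemate tie that must break deterministically.

The seed perturbs only non-structural decimals (<= 0.001 fractional) so
tolerance handling is exercised while every ground-truth count stays fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cif_io import AtomSite, CrystalCell, StructureRecord, write_cif
from .symmetry import orthogonalization_matrix

FIXTURE_KINDS = ("p1_molecule", "cocrystal", "rocksalt", "enantiomer_pair")

JITTER = 1e-3  # max fractional perturbation applied per seed


@dataclass
class FixtureSpec:
    """Ground truth stored alongside the emitted CIF text."""

    kind: str
    cell: CrystalCell
    packed: bool  # whether the pipeline should pack this fixture
    expected: dict = field(default_factory=dict)
    description: str = ""


def _water_offsets(bond: float = 0.96, angle_deg: float = 104.5) -> np.ndarray:
    """Cartesian offsets of O, H, H around the oxygen, in Å."""
    half = math.radians(angle_deg / 2.0)
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [bond * math.sin(half), bond * math.cos(half), 0.0],
            [-bond * math.sin(half), bond * math.cos(half), 0.0],
        ]
    )


def _place(cell: CrystalCell, centroid_frac, cart_offsets) -> np.ndarray:
    """Fractional coordinates of a rigid group centered at ``centroid_frac``."""
    Minv = np.linalg.inv(orthogonalization_matrix(cell))
    offsets = np.asarray(cart_offsets, dtype=float)
    offsets = offsets - offsets.mean(axis=0)
    return np.asarray(centroid_frac, dtype=float) + (Minv @ offsets.T).T


def _chain10() -> np.ndarray:
    """10-atom helical carbon chain: 1.45 Å bonds, compact, no 1-3 contacts."""
    R, phi, h = 1.977, 0.72, 0.4
    k = np.arange(10)
    return np.column_stack([R * np.cos(k * phi), R * np.sin(k * phi), h * k])


def _ring12(bond: float = 1.45) -> np.ndarray:
    """12-membered carbocycle; ring radius set so edges are bond-length."""
    r = bond / (2.0 * math.sin(math.pi / 12.0))
    th = 2.0 * math.pi * np.arange(12) / 12.0
    return np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros(12)])


def _chiral5() -> np.ndarray:
    """5 carbons with no internal mirror symmetry (a chiral fragment)."""
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [1.5, 0.0, 0.0],
            [0.0, 1.5, 0.0],
            [0.0, 0.0, 1.5],
            [2.4, 1.2, 0.0],
        ]
    )


def _sites(groups: list[tuple[str, np.ndarray]], prefix_counts: dict | None = None) -> list[AtomSite]:
    sites = []
    counters: dict[str, int] = {}
    for element, fracs in groups:
        for frac in np.atleast_2d(fracs):
            counters[element] = counters.get(element, 0) + 1
            sites.append(
                AtomSite(
                    label=f"{element}{counters[element]}",
                    element=element,
                    frac=tuple(float(x) for x in frac),
                )
            )
    return sites


def make_fixture(kind: str, seed: int = 0, large_counterion: bool = False) -> tuple[str, FixtureSpec]:
    """Emit CIF text plus its :class:`FixtureSpec` ground truth.

    ``large_counterion`` applies to the cocrystal only and swaps the
    single-atom counterion for a 12-atom one, flipping which fragment the
    size-based selection keeps.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
    rng = np.random.default_rng(seed)

    if kind == "p1_molecule":
        cell = CrystalCell(15.0, 15.0, 15.0, 90.0, 90.0, 90.0)
        fracs = _place(cell, (0.5, 0.5, 0.5), _water_offsets())
        groups = [("O", fracs[:1]), ("H", fracs[1:])]
        symops = ["x,y,z"]
        expected = {
            "sites": 3,
            "expanded": 3,
            "packed": 3,
            "fragment_sizes": [3],
            "primary_natoms": 3,
        }
        desc = "isolated water molecule, P1"
    elif kind == "cocrystal":
        cell = CrystalCell(22.0, 22.0, 22.0, 90.0, 90.0, 90.0)
        symops = ["x,y,z", "-x,-y,-z"]
        chain = _place(cell, (0.25, 0.25, 0.20), _chain10())
        solvent_a = _place(cell, (0.25, 0.62, 0.55), _water_offsets())
        solvent_b = _place(cell, (0.62, 0.25, 0.55), _water_offsets()[:, [2, 0, 1]])
        groups = [("C", chain), ("O", solvent_a[:1]), ("H", solvent_a[1:]),
                  ("O", solvent_b[:1]), ("H", solvent_b[1:])]
        if large_counterion:
            ion = _place(cell, (0.60, 0.60, 0.22), _ring12())
            groups.append(("C", ion))
            nion = 12
        else:
            ion = _place(cell, (0.57, 0.57, 0.25), np.zeros((1, 3)))
            groups.append(("Cl", ion))
            nion = 1
        nsites = 10 + 3 + 3 + nion
        sizes = sorted([10, 10, 3, 3, 3, 3, nion, nion], reverse=True)
        expected = {
            "sites": nsites,
            "expanded": 2 * nsites,
            "packed": 2 * nsites,
            "fragment_sizes": sizes,
            "primary_natoms": max(10, nion),
        }
        desc = "P-1 co-crystal: molecule + 2 solvents + counterion"
    elif kind == "rocksalt":
        cell = CrystalCell(5.64, 5.64, 5.64, 90.0, 90.0, 90.0)
        symops = ["x,y,z", "x+1/2,y+1/2,z", "x+1/2,y,z+1/2", "x,y+1/2,z+1/2"]
        groups = [("Na", np.array([[0.0, 0.0, 0.0]])),
                  ("Cl", np.array([[0.5, 0.5, 0.5]]))]
        expected = {
            "sites": 2,
            "expanded": 8,
            "packed": 27,
            "fragment_sizes": [27],
            "primary_natoms": 27,
        }
        desc = "rock-salt extended solid, explicit F-centering operators"
    else:  # enantiomer_pair
        cell = CrystalCell(18.0, 18.0, 18.0, 90.0, 90.0, 90.0)
        symops = ["x,y,z", "-x,-y,-z"]
        fracs = _place(cell, (0.25, 0.25, 0.25), _chiral5())
        groups = [("C", fracs)]
        expected = {
            "sites": 5,
            "expanded": 10,
            "packed": 10,
            "fragment_sizes": [5, 5],
            "primary_natoms": 5,
        }
        desc = "racemate: chiral fragment + its inversion image"

    sites = _sites(groups)
    if kind != "rocksalt":  # special positions must stay exactly special
        jitter = rng.uniform(-JITTER, JITTER, (len(sites), 3))
        sites = [
            AtomSite(label=s.label, element=s.element,
                     frac=tuple(float(x) for x in np.asarray(s.frac) + jitter[k]))
            for k, s in enumerate(sites)
        ]
    record = StructureRecord(cell=cell, symop_strings=symops, sites=sites,
                             name=f"{kind}_seed{seed}")
    spec = FixtureSpec(kind=kind, cell=cell, packed=(kind == "rocksalt"),
                       expected=expected, description=desc)
    return write_cif(record), spec
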