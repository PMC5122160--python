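"""End-to-end conversion: CIF in, printable STL/VRML out, batch over lists.

One file flows through: read -> symmetry expansion (optionally packed) ->
bond perception -> connected fragments -> selection of the largest fragment
(or every fragment in per-molecule mode) -> ball-and-stick shells -> STL /
VRML serialization. A failure at any stage marks that file failed and the
batch continues; partially written outputs are never left behind (writes go
to a temporary name and are renamed on success).
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import fragments as frg
from . import symmetry as sym
from .cif_io import read_cif
from .mesh import StyleConfig, build_ballstick
from .writers import ExportBundle, write_stl, write_vrml

logger = logging.getLogger("cif2print")

FORMAT_EXTENSIONS = {"vrml": ".wrl", "stl": ".stl"}


@dataclass
class JobConfig:
    """Everything one conversion needs besides the CIF itself."""

    mode: str = "molecular"  # "molecular" | "packed"
    per_molecule: bool = False
    style: StyleConfig = field(default_factory=StyleConfig)
    formats: tuple[str, ...] = ("vrml", "stl")
    output_dir: Path = Path(".")
    dedup_tol: float = sym.DEDUP_TOL
    bond_tol: float = frg.BOND_TOL
    boundary_eps: float = sym.BOUNDARY_EPS
    stl_mode: str = "binary"

    def __post_init__(self) -> None:
        if self.mode not in ("molecular", "packed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.formats:
            raise ValueError("formats must be non-empty")
        for f in self.formats:
            if f not in FORMAT_EXTENSIONS:
                raise ValueError(f"unknown format {f!r}")
        self.output_dir = Path(self.output_dir)


@dataclass
class FileResult:
    """Outcome of converting one CIF."""

    path: str
    status: str  # "ok" | "failed"
    reason: str = ""
    fragments_found: int = 0
    fragments_kept: int = 0
    atoms_total: int = 0
    atoms_kept: int = 0
    outputs: list[Path] = field(default_factory=list)


@dataclass
class BatchReport:
    entries: list[FileResult] = field(default_factory=list)

    @property
    def n_ok(self) -> int:
        return sum(1 for e in self.entries if e.status == "ok")

    @property
    def n_failed(self) -> int:
        return sum(1 for e in self.entries if e.status == "failed")

    @property
    def all_ok(self) -> bool:
        return self.n_failed == 0

    def summary(self) -> str:
        return f"{len(self.entries)} file(s): {self.n_ok} ok, {self.n_failed} failed"


def _write_model(shells, name: str, config: JobConfig, stem: str) -> list[Path]:
    """Serialize one model to every requested format, atomically."""
    bundle = ExportBundle(shells=shells, name=name)
    bundle.validate()  # refuse to write invalid geometry, before any file exists
    written: list[Path] = []
    for fmt in config.formats:
        dest = config.output_dir / f"{stem}{FORMAT_EXTENSIONS[fmt]}"
        tmp = dest.with_name(dest.name + ".tmp")
        try:
            if fmt == "vrml":
                write_vrml(bundle, tmp, force=True)
            else:
                write_stl(bundle, tmp, mode=config.stl_mode, force=True)
            os.replace(tmp, dest)
        except BaseException:
            tmp.unlink(missing_ok=True)
            raise
        written.append(dest)
    return written


def convert_one(cif_path: str | Path, config: JobConfig) -> FileResult:
    """Convert one CIF; never raises for per-file problems (status carries it)."""
    cif_path = Path(cif_path)
    result = FileResult(path=str(cif_path), status="failed")
    config.output_dir.mkdir(parents=True, exist_ok=True)
    stage = "read"
    try:
        record = read_cif(cif_path)
        stage = "expand"
        if config.mode == "packed":
            atoms = sym.pack_cell(record, ranges=(1, 1, 1),
                                  boundary_eps=config.boundary_eps,
                                  dedup_tol=config.dedup_tol)
        else:
            atoms = sym.expand(record, dedup_tol=config.dedup_tol)
        result.atoms_total = len(atoms)
        stage = "bonds"
        bonds = frg.perceive_bonds(atoms, bond_tol=config.bond_tol)
        stage = "fragments"
        frags = frg.find_fragments(atoms, bonds)
        result.fragments_found = len(frags)
        if config.per_molecule:
            kept = frags
        else:
            kept = [frg.select_primary(frags)]
            dropped = len(frags) - 1
            if dropped:
                logger.info("%s: deleted %d smaller/duplicate fragment(s)",
                            cif_path.name, dropped)
            if config.mode == "packed" and kept[0].natoms < len(atoms):
                logger.warning("%s: kept network excludes %d packed atom(s)",
                               cif_path.name, len(atoms) - kept[0].natoms)
        result.fragments_kept = len(kept)
        result.atoms_kept = sum(f.natoms for f in kept)
        stage = "mesh"
        models = []
        for k, fragment in enumerate(kept):
            shells = build_ballstick(fragment, atoms, config.style)
            stem = cif_path.stem if len(kept) == 1 else f"{cif_path.stem}_mol{k:02d}"
            models.append((shells, stem))
        stage = "write"
        for shells, stem in models:
            result.outputs += _write_model(shells, stem, config, stem)
        result.status = "ok"
        result.reason = ""
    except Exception as exc:  # per-file isolation: record, never propagate
        result.status = "failed"
        result.reason = f"{stage}: {exc}"
        logger.error("%s failed at stage %s: %s", cif_path, stage, exc)
    return result


def run_batch(list_file: str | Path, config: JobConfig) -> BatchReport:
    """Process a text list of CIF paths in order; one bad file never aborts.

    Blank lines and ``#`` comments are ignored; relative paths resolve
    against the list file's directory.
    """
    list_file = Path(list_file)
    if not list_file.exists():
        raise FileNotFoundError(f"list file not found: {list_file}")
    report = BatchReport()
    t0 = time.monotonic()
    for raw in list_file.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        path = Path(line)
        if not path.is_absolute():
            path = list_file.parent / path
        entry = convert_one(path, config)
        logger.info("%s: %s%s", entry.path, entry.status,
                    f" ({entry.reason})" if entry.reason else "")
        report.entries.append(entry)
    logger.info("batch done in %.1f s: %s", time.monotonic() - t0, report.summary())
    return report
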