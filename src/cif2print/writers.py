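"""Serialization of shell lists to VRML 2.0 and STL (binary and ASCII).

VRML output uses IndexedFaceSet nodes with per-vertex color exclusively —
never the high-level Sphere/Cylinder/Cone primitives, which 3D-print
toolchains cannot slice and which would otherwise require a post-processing
pass. STL output is geometry-only (the format carries no color); binary STL
follows the 80-byte-header + 50-bytes-per-triangle layout exactly, with
normals recomputed from the vertex winding (right-hand rule).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import CorruptStlError, MeshValidationError
from .mesh import TriangleMesh, validate_shell

VRML_HEADER = "#VRML V2.0 utf8"


@dataclass
class ExportBundle:
    """Shells ready for serialization, plus naming/provenance metadata."""

    shells: list[TriangleMesh]
    name: str = "model"
    units_note: str = "model units are millimetres"

    def validate(self) -> None:
        if not self.shells:
            raise MeshValidationError("refusing to write an empty shell list")
        for k, shell in enumerate(self.shells):
            report = validate_shell(shell)
            if not report.watertight:
                raise MeshValidationError(
                    f"shell {k} of {self.name!r} fails printability: "
                    f"boundary={report.boundary_edges} nonmanifold={report.nonmanifold_edges} "
                    f"oriented={report.oriented} volume={report.signed_volume:.3g} "
                    f"degenerate={report.degenerate_triangles}"
                )


def _fmt(x: float) -> str:
    s = f"{x:.6g}"
    return "0" if s == "-0" else s


def write_vrml(bundle: ExportBundle, destination: str | Path, force: bool = False) -> Path:
    """Write VRML 2.0: one IndexedFaceSet Shape per shell, per-vertex color.

    The file starts with the exact header line ``#VRML V2.0 utf8``;
    coordinate-index runs are -1 terminated; numbers carry 6 significant
    digits. Shells failing validation abort the write unless ``force``.
    """
    if not force:
        bundle.validate()
    elif not bundle.shells:
        raise MeshValidationError("refusing to write an empty shell list")
    out = [VRML_HEADER]
    out.append(f"# {bundle.name} — {bundle.units_note}")
    for shell in bundle.shells:
        pts = " ".join(
            f"{_fmt(x)} {_fmt(y)} {_fmt(z)}," for x, y, z in shell.vertices
        )
        idx = " ".join(
            f"{a} {b} {c} -1," for a, b, c in shell.triangles
        )
        cols = " ".join(
            f"{_fmt(r / 255.0)} {_fmt(g / 255.0)} {_fmt(b / 255.0)},"
            for r, g, b in shell.vertex_colors
        )
        out.append(
            "Shape {\n"
            "  geometry IndexedFaceSet {\n"
            "    solid TRUE\n"
            "    ccw TRUE\n"
            f"    coord Coordinate {{ point [ {pts} ] }}\n"
            f"    coordIndex [ {idx} ]\n"
            f"    color Color {{ color [ {cols} ] }}\n"
            "    colorPerVertex TRUE\n"
            "  }\n"
            "}"
        )
    dest = Path(destination)
    dest.write_text("\n".join(out) + "\n", encoding="utf-8")
    return dest


def _triangle_soup(bundle: ExportBundle) -> tuple[np.ndarray, np.ndarray]:
    """All shells concatenated: per-triangle vertices (n,3,3) and unit normals."""
    tris = np.concatenate(
        [shell.vertices[shell.triangles] for shell in bundle.shells], axis=0
    )
    n = np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return tris, n / norm


def write_stl(bundle: ExportBundle, destination: str | Path, mode: str = "binary",
              force: bool = False) -> Path:
    """Write STL; all shells concatenated into one solid (STL has no color).

    Binary layout: 80-byte header, little-endian uint32 triangle count, then
    50 bytes per triangle (normal, 3 vertices as float32, zero attribute) —
    file size is exactly 84 + 50·n bytes. ASCII mode writes the standard
    ``solid``/``facet`` dialect. Normals are recomputed from winding.
    """
    if mode not in ("binary", "ascii"):
        raise ValueError(f"unknown STL mode {mode!r}")
    if not force:
        bundle.validate()
    elif not bundle.shells:
        raise MeshValidationError("refusing to write an empty shell list")
    tris, normals = _triangle_soup(bundle)
    if not (np.isfinite(tris).all() and np.isfinite(normals).all()):
        raise MeshValidationError("non-finite coordinates; refusing to serialize")
    dest = Path(destination)
    if mode == "binary":
        header = f"cif2print {bundle.name}".encode("utf-8", "replace")[:80]
        header = header.ljust(80, b"\0")
        rec = np.zeros(len(tris), dtype=np.dtype([("data", "<f4", (12,)), ("attr", "<u2")]))
        rec["data"][:, 0:3] = normals
        rec["data"][:, 3:12] = tris.reshape(-1, 9)
        with open(dest, "wb") as fh:
            fh.write(header)
            fh.write(struct.pack("<I", len(tris)))
            fh.write(rec.tobytes())
    else:
        with open(dest, "w", encoding="ascii") as fh:
            fh.write(f"solid {bundle.name}\n")
            for nvec, tri in zip(normals, tris):
                fh.write(f"  facet normal {_fmt(nvec[0])} {_fmt(nvec[1])} {_fmt(nvec[2])}\n")
                fh.write("    outer loop\n")
                for v in tri:
                    fh.write(f"      vertex {_fmt(v[0])} {_fmt(v[1])} {_fmt(v[2])}\n")
                fh.write("    endloop\n")
                fh.write("  endfacet\n")
            fh.write(f"endsolid {bundle.name}\n")
    return dest


def _read_stl_ascii(text: str) -> tuple[np.ndarray, np.ndarray]:
    normals: list[list[float]] = []
    tris: list[list[list[float]]] = []
    current: list[list[float]] = []
    saw_endsolid = False
    for raw in text.splitlines():
        tokens = raw.split()
        if not tokens:
            continue
        if tokens[0] == "facet" and len(tokens) >= 5 and tokens[1] == "normal":
            normals.append([float(t) for t in tokens[2:5]])
            current = []
        elif tokens[0] == "vertex":
            if len(tokens) != 4:
                raise CorruptStlError(f"bad vertex line: {raw!r}")
            current.append([float(t) for t in tokens[1:4]])
        elif tokens[0] == "endfacet":
            if len(current) != 3:
                raise CorruptStlError("facet without exactly 3 vertices")
            tris.append(current)
        elif tokens[0] == "endsolid":
            saw_endsolid = True
    if not saw_endsolid:
        raise CorruptStlError("ASCII STL missing endsolid")
    if len(normals) != len(tris):
        raise CorruptStlError("facet/normal count mismatch")
    if not tris:
        return np.zeros((0, 3)), np.zeros((0, 3, 3))
    return np.asarray(normals), np.asarray(tris)


def read_stl(source: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read binary or ASCII STL; returns (normals (n,3), triangles (n,3,3)).

    A file is treated as ASCII iff it starts with ``solid`` and parses fully
    as the ASCII dialect; otherwise it is read as binary, and a body whose
    byte length disagrees with 84 + 50·count raises :class:`CorruptStlError`.
    """
    data = Path(source).read_bytes()
    if data[:5] == b"solid":
        try:
            return _read_stl_ascii(data.decode("ascii", errors="strict"))
        except (CorruptStlError, UnicodeDecodeError, ValueError):
            pass  # "solid"-prefixed binary files exist; fall through
    if len(data) < 84:
        raise CorruptStlError(f"binary STL truncated ({len(data)} bytes < 84)")
    (count,) = struct.unpack_from("<I", data, 80)
    if len(data) != 84 + 50 * count:
        raise CorruptStlError(
            f"binary STL size {len(data)} != 84 + 50×{count} declared triangles"
        )
    rec = np.frombuffer(data, dtype=np.dtype([("data", "<f4", (12,)), ("attr", "<u2")]),
                        count=count, offset=84)
    payload = rec["data"].astype(np.float64)
    return payload[:, 0:3], payload[:, 3:12].reshape(-1, 3, 3)
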