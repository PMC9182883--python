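"""Reading, validation and writing of triangle meshes.

A fruit or endocarp surface is held as an indexed triangle mesh in a
right-handed frame with +Z up and coordinates in centimetres.  Parsing and
serialisation of the three interchange formats (STL ascii/binary, OBJ,
ascii PLY) are delegated to :mod:`trimesh`; load-time cleaning (duplicate
vertex merging, degenerate face removal) and the validation report are
implemented here so their semantics are exactly those documented below.

Validation is deliberately separated from computation: a mesh that is not
watertight loads fine and supports area/dimension traits; only volume and
centre-of-gravity operations reject it (see :mod:`olivemorph.mesh_morphometrics`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import MeshFormatError, ParameterError

#: vertices closer than this (cm) are merged at load time; far below the
#: ~0.005 cm point accuracy of structured-light desktop scanners.
MERGE_TOLERANCE_CM = 1e-9

_EXTENSIONS = {".stl": "stl", ".obj": "obj", ".ply": "ply"}


@dataclass
class TriangleMesh:
    """Indexed triangle surface of one fruit or endocarp.

    Attributes
    ----------
    vertices : (n, 3) float array, cm
    faces : (m, 3) int array
        Vertex-index triples; counter-clockwise order seen from outside,
        i.e. the right-hand rule gives the outward normal.
    name : str
        Sample identifier, carried through I/O where the format allows.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), self.name)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)


@dataclass
class MeshValidationReport:
    """Geometric soundness summary produced by :func:`validate_mesh`."""

    watertight: bool
    consistently_oriented: bool
    n_vertices: int
    n_faces: int
    n_degenerate_removed: int = 0
    total_signed_volume_sign: int = 0  # +1, -1 or 0
    n_open_edges: int = field(default=0)


def _face_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v0, v1, v2 = (vertices[faces[:, i]] for i in range(3))
    return 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)


def clean_mesh(
    vertices: np.ndarray,
    faces: np.ndarray,
    name: str = "",
    merge_tol: float = MERGE_TOLERANCE_CM,
) -> tuple[TriangleMesh, int]:
    """Merge near-duplicate vertices and drop degenerate faces.

    Returns the cleaned mesh and the number of faces removed.  A face is
    degenerate when it repeats a vertex index (after merging) or has zero
    area below float tolerance.
    """
    vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
    faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
    if not np.all(np.isfinite(vertices)):
        raise MeshFormatError(f"{name!r}: non-finite vertex coordinates")
    if len(faces) and (faces.min() < 0 or faces.max() >= len(vertices)):
        raise MeshFormatError(f"{name!r}: face index out of range")

    # quantize to the merge tolerance, then unique
    keys = np.round(vertices / merge_tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    new_vertices = vertices[np.sort(first)]
    # remap unique-order -> sorted-first order
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_faces = rank[inverse][faces]

    n_before = len(new_faces)
    distinct = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 0] != new_faces[:, 2])
    )
    new_faces = new_faces[distinct]
    if len(new_faces):
        areas = _face_areas(new_vertices, new_faces)
        new_faces = new_faces[areas > 1e-14]
    n_removed = n_before - len(new_faces)

    # drop unreferenced vertices
    used = np.unique(new_faces) if len(new_faces) else np.array([], dtype=np.int64)
    remap = -np.ones(len(new_vertices), dtype=np.int64)
    remap[used] = np.arange(len(used))
    mesh = TriangleMesh(new_vertices[used], remap[new_faces], name=name)
    return mesh, n_removed


def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        if fmt not in ("stl", "obj", "ply"):
            raise ParameterError(f"unknown mesh format {fmt!r}")
        return fmt
    ext = _EXTENSIONS.get(path.suffix.lower())
    if ext:
        return ext
    with open(path, "rb") as fh:
        head = fh.read(80)
    if head.startswith(b"ply"):
        return "ply"
    if head.startswith(b"solid"):
        return "stl"
    raise MeshFormatError(f"cannot detect mesh format of {path}")


def read_mesh(
    path: str | Path,
    format: str = "auto",
    units: str = "cm",
    name: str | None = None,
) -> tuple[TriangleMesh, int]:
    """Load a mesh file and return ``(mesh, n_degenerate_removed)``.

    File coordinates are taken to be centimetres unless ``units='mm'``,
    which rescales by 0.1 on load.  Degenerate faces are dropped and
    vertices within :data:`MERGE_TOLERANCE_CM` are merged.

    Raises
    ------
    MeshFormatError
        If the file cannot be parsed or is empty after cleaning.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    fmt = _detect_format(path, format)
    try:
        loaded = trimesh.load(str(path), file_type=fmt, force="mesh", process=False)
    except Exception as exc:  # trimesh raises assorted types on bad input
        raise MeshFormatError(f"failed to parse {path}: {exc}") from exc
    if loaded.vertices.size == 0 or loaded.faces.size == 0:
        raise MeshFormatError(f"{path}: empty mesh")

    if name is None:
        name = loaded.metadata.get("name") or path.stem
    mesh, n_removed = clean_mesh(loaded.vertices, loaded.faces, name=name)
    if units == "mm":
        mesh.vertices *= 0.1
    elif units != "cm":
        raise ParameterError(f"units must be 'cm' or 'mm', got {units!r}")
    if mesh.n_faces == 0:
        raise MeshFormatError(f"{path}: no valid faces after cleaning")
    return mesh, n_removed


def _edge_counts(faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Undirected edges of the face list and their multiplicities."""
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    und = np.sort(edges, axis=1)
    uniq, counts = np.unique(und, axis=0, return_counts=True)
    return uniq, counts


def validate_mesh(mesh: TriangleMesh, n_degenerate_removed: int = 0) -> MeshValidationReport:
    """Report watertightness and orientation consistency.

    Watertight means every undirected edge is shared by exactly two faces.
    Consistent orientation means adjacent faces traverse each shared edge
    in opposite directions, i.e. no directed edge occurs twice.  Never
    raises: meshes of any quality get a report.
    """
    faces = mesh.faces
    if len(faces) == 0:
        return MeshValidationReport(False, False, mesh.n_vertices, 0, n_degenerate_removed)
    _, counts = _edge_counts(faces)
    watertight = bool(np.all(counts == 2))
    n_open = int(np.sum(counts != 2))

    directed = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    _, dcounts = np.unique(directed, axis=0, return_counts=True)
    oriented = bool(np.all(dcounts == 1))

    sign = 0
    if watertight:
        v = mesh.vertices
        v0, v1, v2 = v[faces[:, 0]], v[faces[:, 1]], v[faces[:, 2]]
        signed = np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0
        sign = int(np.sign(signed)) if abs(signed) > 1e-14 else 0

    return MeshValidationReport(
        watertight=watertight,
        consistently_oriented=oriented,
        n_vertices=mesh.n_vertices,
        n_faces=mesh.n_faces,
        n_degenerate_removed=n_degenerate_removed,
        total_signed_volume_sign=sign,
        n_open_edges=n_open,
    )


def _export_ply(mesh: TriangleMesh) -> str:
    # ascii PLY with float64 coordinates, so round-trips preserve traits
    # to ~1e-15 (the float32 vertices of stock writers lose ~1e-7)
    head = (
        "ply\nformat ascii 1.0\n"
        f"comment {mesh.name}\n"
        f"element vertex {mesh.n_vertices}\n"
        "property double x\nproperty double y\nproperty double z\n"
        f"element face {mesh.n_faces}\n"
        "property list uchar int vertex_indices\nend_header\n"
    )
    vlines = "\n".join(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}" for v in mesh.vertices)
    flines = "\n".join(f"3 {f[0]} {f[1]} {f[2]}" for f in mesh.faces)
    return head + vlines + "\n" + flines + "\n"


def _export_obj(mesh: TriangleMesh) -> str:
    lines = [f"o {mesh.name}" if mesh.name else "o mesh"]
    for v in mesh.vertices:
        lines.append(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}")
    for f in mesh.faces:
        lines.append(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}")
    return "\n".join(lines) + "\n"


def write_mesh(
    mesh: TriangleMesh,
    path: str | Path,
    format: str = "auto",
    encoding: str = "binary",
) -> Path:
    """Write a mesh to STL (ascii or binary), OBJ, or ascii PLY.

    Round-trip through :func:`read_mesh` preserves vertices and faces to
    float precision; OBJ additionally preserves the sample name in the
    object tag.
    """
    path = Path(path)
    fmt = _EXTENSIONS.get(path.suffix.lower()) if format == "auto" else format
    if fmt not in ("stl", "obj", "ply"):
        raise ParameterError(f"unknown mesh format {fmt!r}")
    tm = mesh.to_trimesh()
    try:
        if fmt == "obj":
            path.write_text(_export_obj(mesh), encoding="utf-8")
        elif fmt == "stl" and encoding == "ascii":
            path.write_text(trimesh.exchange.stl.export_stl_ascii(tm))
        elif fmt == "stl":
            path.write_bytes(trimesh.exchange.stl.export_stl(tm))
        else:  # ply, always ascii for text-friendly artifacts
            path.write_text(_export_ply(mesh))
    except OSError as exc:
        raise MeshFormatError(f"cannot write {path}: {exc}") from exc
    return path
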