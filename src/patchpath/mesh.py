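"""Triangulated surface meshes and STL input/output.

The internal representation is a plain vertex/face array pair in millimetres.
STL files (binary and ASCII dialects) are the only external mesh format; file
normals are never trusted — normals are always recomputed from face winding.
On load the mesh is cleaned: exactly coincident (within ``MERGE_TOL``)
vertices are merged and degenerate (near-zero-area) faces are dropped.
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

#: Absolute vertex-merge tolerance (mm); far below the 0.05 mm repeatability
#: of the target hardware, so merging never alters printable geometry.
MERGE_TOL = 1e-9
#: Faces with area at or below this (mm^2) are degenerate and removed.
AREA_TOL = 1e-12

_BINARY_RECORD = np.dtype(
    [("normal", "<f4", (3,)), ("vertices", "<f4", (3, 3)), ("attr", "<u2")]
)


class MeshError(ValueError):
    """Invalid mesh content (empty, non-finite, bad indices)."""


class STLParseError(MeshError):
    """Malformed or truncated STL file."""


@dataclass(frozen=True)
class TriangleMesh:
    """Triangle surface mesh in millimetres.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of 0-based vertex indices
    n_degenerate_removed : number of degenerate faces dropped by load-time
        cleaning (metadata, not part of the geometry).
    """

    vertices: np.ndarray
    faces: np.ndarray
    n_degenerate_removed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "vertices", np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        )
        object.__setattr__(
            self, "faces", np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        )

    # -- derived geometry -------------------------------------------------

    @property
    def face_normals(self) -> np.ndarray:
        """Unit normals recomputed from winding, shape (m, 3)."""
        tri = self.vertices[self.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    @property
    def face_areas(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        return 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) array: componentwise [min; max] over vertices (mm)."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def translated(self, offset) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices + np.asarray(offset, dtype=np.float64),
            self.faces,
            self.n_degenerate_removed,
        )

    def validate(self) -> None:
        """Raise :class:`MeshError` if any structural invariant is violated."""
        if self.faces.shape[0] == 0:
            raise MeshError("mesh has no faces")
        if not np.isfinite(self.vertices).all():
            raise MeshError("mesh has non-finite vertex coordinates")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= len(
            self.vertices
        ):
            raise MeshError("face index out of range")
        if (self.face_areas <= AREA_TOL).any():
            raise MeshError("mesh contains degenerate faces")


@dataclass(frozen=True)
class MeshReport:
    """Summary of a loaded mesh: counts, cleaning statistics and bounds."""

    n_vertices: int
    n_faces: int
    n_degenerate_removed: int
    bounds: np.ndarray  # (2, 3) [min; max] in mm


def clean_mesh(vertices: np.ndarray, faces: np.ndarray) -> TriangleMesh:
    """Merge duplicate vertices (``MERGE_TOL``) and drop degenerate faces."""
    vertices = np.asarray(vertices, dtype=np.float64).reshape(-1, 3)
    faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
    if not np.isfinite(vertices).all():
        raise MeshError("non-finite vertex coordinates")
    # Quantise at the merge tolerance, then unique rows.  Exact duplicates
    # (the common STL case: each triangle carries its own vertex copies)
    # always merge; near-duplicates within 1e-9 mm merge unless they straddle
    # a quantisation boundary, which is irrelevant at printing scale.
    key = np.round(vertices / MERGE_TOL).astype(np.int64)
    _, first_idx, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    merged = vertices[first_idx]
    remapped = inverse[faces]

    tri = merged[remapped]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    keep = areas > AREA_TOL
    n_removed = int((~keep).sum())
    return TriangleMesh(merged, remapped[keep], n_degenerate_removed=n_removed)


def mesh_summary(mesh: TriangleMesh) -> MeshReport:
    mesh.validate()
    return MeshReport(
        n_vertices=len(mesh.vertices),
        n_faces=len(mesh.faces),
        n_degenerate_removed=mesh.n_degenerate_removed,
        bounds=mesh.bounds,
    )


# -- STL reading ----------------------------------------------------------


def _is_ascii_stl(raw: bytes) -> bool:
    # "solid" header alone is unreliable (binary exporters write it too);
    # fall back to the binary size check.
    if not raw.lstrip()[:5].lower() == b"solid":
        return False
    if len(raw) >= 84:
        (n_tri,) = struct.unpack_from("<I", raw, 80)
        if len(raw) == 84 + 50 * n_tri:
            return False
    return True


def _parse_binary(raw: bytes, path: str) -> tuple[np.ndarray, np.ndarray]:
    if len(raw) < 84:
        raise STLParseError(
            f"{path}: truncated binary STL — need 84 header bytes, file ends at byte {len(raw)}"
        )
    (n_tri,) = struct.unpack_from("<I", raw, 80)
    expected = 84 + 50 * n_tri
    if len(raw) < expected:
        raise STLParseError(
            f"{path}: truncated binary STL — {n_tri} triangles need {expected} bytes, "
            f"file ends at byte {len(raw)}"
        )
    records = np.frombuffer(raw, dtype=_BINARY_RECORD, count=n_tri, offset=84)
    vertices = records["vertices"].reshape(-1, 3).astype(np.float64)
    faces = np.arange(len(vertices), dtype=np.int64).reshape(-1, 3)
    return vertices, faces


def _parse_ascii(raw: bytes, path: str) -> tuple[np.ndarray, np.ndarray]:
    coords: list[float] = []
    offset = 0
    for line in raw.splitlines(keepends=True):
        stripped = line.strip().lower()
        if stripped.startswith(b"vertex"):
            parts = stripped.split()
            if len(parts) != 4:
                raise STLParseError(
                    f"{path}: malformed vertex line at byte {offset}: {line!r}"
                )
            try:
                coords.extend(float(p) for p in parts[1:])
            except ValueError:
                raise STLParseError(
                    f"{path}: non-numeric vertex at byte {offset}: {line!r}"
                ) from None
        offset += len(line)
    if len(coords) == 0 or len(coords) % 9 != 0:
        raise STLParseError(
            f"{path}: ASCII STL ended at byte {offset} with {len(coords) // 3} vertices "
            "(not a multiple of 3 — truncated facet?)"
        )
    vertices = np.array(coords, dtype=np.float64).reshape(-1, 3)
    faces = np.arange(len(vertices), dtype=np.int64).reshape(-1, 3)
    return vertices, faces


def read_stl(path: Union[str, Path]) -> TriangleMesh:
    """Read a binary or ASCII STL file (autodetected) into a cleaned mesh.

    Coordinates are interpreted as millimetres (STL carries no unit
    metadata).  Stored facet normals are ignored.

    Raises
    ------
    STLParseError
        On truncated or malformed files (the message names the byte offset).
    MeshError
        If no valid face survives cleaning.
    """
    raw = Path(path).read_bytes()
    if _is_ascii_stl(raw):
        vertices, faces = _parse_ascii(raw, str(path))
    else:
        vertices, faces = _parse_binary(raw, str(path))
    mesh = clean_mesh(vertices, faces)
    if len(mesh.faces) == 0:
        raise MeshError(f"{path}: no non-degenerate faces after cleaning")
    return mesh


# -- STL writing ----------------------------------------------------------


def write_stl(mesh: TriangleMesh, path: Union[str, Path], dialect: str = "binary") -> None:
    """Write ``mesh`` to ``path`` as binary (default) or ASCII STL.

    Round trip ``read_stl(write_stl(m))`` reproduces vertices and faces to
    1e-6 mm (binary STL stores float32).
    """
    mesh.validate()
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"unknown STL dialect: {dialect!r}")
    tri = mesh.vertices[mesh.faces]
    normals = mesh.face_normals
    if dialect == "binary":
        records = np.zeros(len(tri), dtype=_BINARY_RECORD)
        records["normal"] = normals.astype(np.float32)
        records["vertices"] = tri.astype(np.float32)
        with open(path, "wb") as fh:
            fh.write(b"patchpath binary STL".ljust(80, b" "))
            fh.write(struct.pack("<I", len(tri)))
            fh.write(records.tobytes())
    else:
        buf = io.StringIO()
        buf.write("solid patchpath\n")
        for n, t in zip(normals, tri):
            buf.write(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}\n")
            buf.write("    outer loop\n")
            for v in t:
                buf.write(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
            buf.write("    endloop\n  endfacet\n")
        buf.write("endsolid patchpath\n")
        Path(path).write_text(buf.getvalue())
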