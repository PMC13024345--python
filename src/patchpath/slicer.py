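"""Plane–mesh slicing: surface contour extraction for conformal toolpaths.

A family of parallel planes normal to the x- or y-axis is intersected with
the upward-facing triangles of a surface mesh.  Each plane–triangle
intersection is a short 3D segment; segments are chained into maximal
polylines by endpoint matching and ordered monotonically along the in-plane
sweep coordinate, then resampled to a maximum spatial step so the downstream
arm controller receives waypoints no farther apart than its validated
discretization step.

Tolerance policy: geometric predicates use ``GEOM_TOL`` (1e-9 mm), endpoint
chaining uses ``CHAIN_TOL`` (1e-6 mm) — both far below the 0.05 mm hardware
repeatability.  Signed distances within ``GEOM_TOL`` of zero are classed as
*positive* (a symbolic perturbation), which implements the coplanar policy:
a triangle lying in the slicing plane contributes nothing, and a plane
passing exactly through a shared mesh edge yields that edge exactly once,
from the triangle below it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
from scipy.spatial import cKDTree

from .mesh import TriangleMesh, AREA_TOL

GEOM_TOL = 1e-9
CHAIN_TOL = 1e-6

_AXES = {"x": np.array([1.0, 0.0, 0.0]), "y": np.array([0.0, 1.0, 0.0])}


class SliceError(ValueError):
    """Slicing precondition violated (degenerate input, empty family)."""


@dataclass(frozen=True)
class Plane:
    """Plane {p : normal . p = offset} with unit normal."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=np.float64)
        length = np.linalg.norm(n)
        if abs(length - 1.0) > 1e-12:
            if length == 0:
                raise SliceError("plane normal must be nonzero")
            n = n / length
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "offset", float(self.offset))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.normal - self.offset


@dataclass(frozen=True)
class PlaneFamily:
    """Uniformly spaced parallel planes normal to a horizontal axis."""

    axis: str  # "x" | "y"
    offsets: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        if self.axis not in _AXES:
            raise SliceError(f"axis must be 'x' or 'y', got {self.axis!r}")
        off = np.asarray(self.offsets, dtype=np.float64)
        if len(off) == 0:
            raise SliceError("empty plane family")
        d = np.diff(off)
        if len(d) and (np.any(d <= 0) or np.ptp(d) > 1e-9):
            raise SliceError("offsets must be strictly increasing with uniform spacing")
        object.__setattr__(self, "offsets", off)

    @property
    def planes(self) -> list[Plane]:
        return [Plane(_AXES[self.axis], o) for o in self.offsets]


@dataclass(frozen=True)
class SurfacePolyline:
    """Ordered points on the mesh surface within one slicing plane."""

    points: np.ndarray  # (k, 3) mm
    source_plane: Plane

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "points", np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        )

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def reversed(self) -> "SurfacePolyline":
        return SurfacePolyline(self.points[::-1], self.source_plane)


def build_plane_family(bounds: np.ndarray, axis: str, spacing: float) -> PlaneFamily:
    """Interior planes at min + k*spacing, k = 1..floor(span/spacing - eps).

    Boundary-touching planes are excluded, making plane counts deterministic:
    a span of [0, 10] at 1 mm spacing gives 9 planes at offsets 1..9.
    """
    if spacing <= 0:
        raise SliceError("spacing must be positive")
    if axis not in _AXES:
        raise SliceError(f"axis must be 'x' or 'y', got {axis!r}")
    bounds = np.asarray(bounds, dtype=np.float64)
    ax = 0 if axis == "x" else 1
    lo, hi = bounds[0, ax], bounds[1, ax]
    span = hi - lo
    if span <= spacing:
        raise SliceError(
            f"mesh span {span:.6g} mm along {axis} admits no interior plane at "
            f"spacing {spacing:.6g} mm"
        )
    k_max = int(math.floor(span / spacing - 1e-9))
    offsets = lo + spacing * np.arange(1, k_max + 1)
    return PlaneFamily(axis=axis, offsets=offsets, spacing=float(spacing))


def intersect_plane_triangle(plane: Plane, tri: np.ndarray):
    """Intersect one plane with one triangle.

    Returns a (2, 3) segment or ``None``.  Vertex-touch and in-plane cases
    are resolved by the perturbation rule (distance within GEOM_TOL of zero
    counts as positive); segments shorter than GEOM_TOL are suppressed.
    """
    tri = np.asarray(tri, dtype=np.float64).reshape(3, 3)
    area = 0.5 * np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0]))
    if area <= AREA_TOL:
        raise SliceError("degenerate triangle")
    d = plane.signed_distance(tri)
    side = np.where(d >= -GEOM_TOL, 1, -1)
    if side.sum() in (3, -3):  # all on one side (coplanar counts as above)
        return None
    pts = []
    for i, j in ((0, 1), (1, 2), (2, 0)):
        if side[i] != side[j]:
            t = d[i] / (d[i] - d[j])
            pts.append(tri[i] + t * (tri[j] - tri[i]))
    seg = np.array(pts)
    if len(seg) != 2 or np.linalg.norm(seg[1] - seg[0]) < GEOM_TOL:
        return None
    return seg


def _sweep_index(plane: Plane) -> int:
    # X-normal plane sweeps along y; Y-normal plane sweeps along x.
    return 1 if abs(plane.normal[0]) >= abs(plane.normal[1]) else 0


def _chain_segments(segments: list[np.ndarray], plane: Plane) -> list[np.ndarray]:
    """Chain segments into maximal polylines by endpoint matching (CHAIN_TOL)."""
    if not segments:
        return []
    ends = np.vstack([s for s in segments])  # (2k, 3)
    tree = cKDTree(ends)
    # union-find over coincident endpoints
    parent = np.arange(len(ends))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in tree.query_pairs(CHAIN_TOL):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    node_of = np.array([find(i) for i in range(len(ends))])
    # adjacency: node -> list of (edge_id, other_node)
    adj: dict[int, list[tuple[int, int]]] = {}
    n_seg = len(segments)
    for e in range(n_seg):
        a, b = node_of[2 * e], node_of[2 * e + 1]
        adj.setdefault(a, []).append((e, b))
        adj.setdefault(b, []).append((e, a))

    used = np.zeros(n_seg, dtype=bool)

    def walk(start: int) -> list[int]:
        seq = [start]
        cur = start
        while True:
            nxt = None
            for e, other in adj[cur]:
                if not used[e]:
                    used[e] = True
                    nxt = other
                    break
            if nxt is None:
                return seq
            seq.append(nxt)
            cur = nxt

    polylines = []
    # open chains first (odd-degree endpoints), then leftover cycles
    degree = {n: sum(1 for e, _ in lst if True) for n, lst in adj.items()}
    starts = [n for n, lst in adj.items() if len(lst) % 2 == 1]
    for s in starts:
        if any(not used[e] for e, _ in adj[s]):
            polylines.append(walk(s))
    for n in adj:
        while any(not used[e] for e, _ in adj[n]):
            polylines.append(walk(n))

    return [ends[np.array(seq)] for seq in polylines]


def _split_monotone(points: np.ndarray, sweep: int) -> list[np.ndarray]:
    """Split a chained polyline at sweep-coordinate reversals; orient ascending."""
    if len(points) < 3:
        pieces = [points]
    else:
        c = points[:, sweep]
        sign = np.sign(np.diff(c))
        # zero-steps inherit the previous direction
        for i in range(1, len(sign)):
            if sign[i] == 0:
                sign[i] = sign[i - 1]
        breaks = [i + 1 for i in range(1, len(sign)) if sign[i] != 0 and sign[i - 1] != 0 and sign[i] != sign[i - 1]]
        pieces = []
        prev = 0
        for b in breaks:
            pieces.append(points[prev : b + 1])
            prev = b
        pieces.append(points[prev:])
    out = []
    for p in pieces:
        if len(p) < 2:
            continue
        if p[-1, sweep] < p[0, sweep]:
            p = p[::-1]
        out.append(p)
    return out


def slice_mesh(mesh: TriangleMesh, plane: Plane, upward_only: bool = True) -> list[SurfacePolyline]:
    """Intersect a mesh with one plane, returning ordered surface polylines.

    Only upward-facing triangles (normal . z > 0) participate by default —
    deposition is from above with a vertical nozzle, so downward-facing
    geometry can never be printed.  Disconnected intersection components
    yield separate polylines; non-monotone contours are split at sweep
    reversals.
    """
    faces = mesh.faces
    if upward_only:
        faces = faces[mesh.face_normals[:, 2] > 0]
    if len(faces) == 0:
        return []
    d = plane.signed_distance(mesh.vertices)
    side = np.where(d >= -GEOM_TOL, 1, -1)
    fs = side[faces]
    candidates = faces[np.abs(fs.sum(axis=1)) != 3]
    segments = []
    for f in candidates:
        seg = intersect_plane_triangle(plane, mesh.vertices[f])
        if seg is not None:
            segments.append(seg)
    sweep = _sweep_index(plane)
    polylines = []
    for chained in _chain_segments(segments, plane):
        for piece in _split_monotone(chained, sweep):
            # drop consecutive duplicates introduced by node merging
            keep = np.ones(len(piece), dtype=bool)
            keep[1:] = np.linalg.norm(np.diff(piece, axis=0), axis=1) > GEOM_TOL
            piece = piece[keep]
            if len(piece) >= 2:
                polylines.append(SurfacePolyline(piece, plane))
    polylines.sort(key=lambda p: p.points[0, sweep])
    return polylines


def slice_mesh_family(mesh: TriangleMesh, family: PlaneFamily,
                      upward_only: bool = True) -> list[SurfacePolyline]:
    """All polylines of a plane family, in plane-offset order."""
    out: list[SurfacePolyline] = []
    for plane in family.planes:
        out.extend(slice_mesh(mesh, plane, upward_only=upward_only))
    return out


def resample_polyline(poly: SurfacePolyline, max_step: float) -> SurfacePolyline:
    """Subdivide chords so consecutive spacing is at most ``max_step``.

    Each original segment of length L is split into ceil(L / max_step)
    equal parts; original points (hence first and last) are preserved and
    all inserted points lie exactly on the original polyline.
    """
    if max_step <= 0:
        raise SliceError("max_step must be positive")
    pts = poly.points
    if len(pts) < 2:
        raise SliceError("cannot resample a single-point polyline")
    lengths = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if (lengths <= max_step + GEOM_TOL).all():
        return poly
    out = [pts[0]]
    for i, L in enumerate(lengths):
        n_div = max(1, math.ceil(L / max_step - 1e-12))
        for k in range(1, n_div + 1):
            out.append(pts[i] + (k / n_div) * (pts[i + 1] - pts[i]))
    return SurfacePolyline(np.array(out), poly.source_plane)


# -- export ---------------------------------------------------------------


def polylines_to_csv(polylines: Sequence[SurfacePolyline], path: Union[str, Path]) -> None:
    """CSV export: one row per point (polyline id, x, y, z to 6 decimals)."""
    with open(path, "w") as fh:
        fh.write("polyline,x_mm,y_mm,z_mm\n")
        for i, poly in enumerate(polylines):
            for p in poly.points:
                fh.write(f"{i},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f}\n")


def polylines_to_json(polylines: Sequence[SurfacePolyline], path: Union[str, Path]) -> None:
    payload = [
        {
            "plane": {"normal": poly.source_plane.normal.tolist(),
                      "offset": poly.source_plane.offset},
            "points": [[round(c, 9) for c in p] for p in poly.points.tolist()],
        }
        for poly in polylines
    ]
    Path(path).write_text(json.dumps(payload, indent=1))
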