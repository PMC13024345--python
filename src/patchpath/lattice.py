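"""Lattice deposition-path assembly.

Two orthogonal families of surface polylines (x-normal and y-normal slicing
planes) are combined into a single ordered deposition path: within each
family the scan direction alternates plane by plane (serpentine, minimising
travel), consecutive lines are joined by straight travel moves — the
shortest 3D vector between the previous end and the next start — and every
deposit line is resampled so consecutive waypoints are no farther apart
than the validated spatial step S.

On a flat plate the result degenerates to the classic planar grid infill
with pore pitch equal to the interplanar distance d; on curved patches the
same construction yields a reticulated scaffold conforming to the surface.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .mesh import TriangleMesh
from .slicer import (
    SliceError,
    SurfacePolyline,
    build_plane_family,
    resample_polyline,
    slice_mesh_family,
)


class PathError(ValueError):
    """Lattice path cannot be built (mesh too small, empty path)."""


@dataclass(frozen=True)
class PathPoint:
    """One waypoint: where the nozzle goes and how it gets there.

    ``move`` is the move type *into* this point: ``deposit`` extrudes along
    the preceding segment, ``travel`` is a non-extruding jump.
    """

    position: np.ndarray
    move: str  # "deposit" | "travel"

    def __post_init__(self) -> None:
        p = np.asarray(self.position, dtype=np.float64).reshape(3)
        if not np.isfinite(p).all():
            raise PathError("non-finite path point")
        if self.move not in ("deposit", "travel"):
            raise PathError(f"unknown move type {self.move!r}")
        object.__setattr__(self, "position", p)


@dataclass(frozen=True)
class LatticePath:
    """Ordered conformal lattice path plus the parameters that built it."""

    points: tuple[PathPoint, ...]
    interplanar_distance: float
    max_step: float
    n_x_lines: int
    n_y_lines: int

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.points])

    @property
    def deposit_positions(self) -> np.ndarray:
        return np.array([p.position for p in self.points if p.move == "deposit"])

    def translated(self, offset) -> "LatticePath":
        off = np.asarray(offset, dtype=np.float64)
        return LatticePath(
            tuple(PathPoint(p.position + off, p.move) for p in self.points),
            self.interplanar_distance, self.max_step, self.n_x_lines, self.n_y_lines,
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("index,x_mm,y_mm,z_mm,move\n")
            for i, p in enumerate(self.points):
                x, y, z = p.position
                fh.write(f"{i},{x:.6f},{y:.6f},{z:.6f},{p.move}\n")

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "interplanar_distance_mm": self.interplanar_distance,
            "max_step_mm": self.max_step,
            "n_x_lines": self.n_x_lines,
            "n_y_lines": self.n_y_lines,
            "points": [
                {"position": [round(c, 9) for c in p.position.tolist()], "move": p.move}
                for p in self.points
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def serpentine_order(polylines: Sequence[SurfacePolyline]) -> list[SurfacePolyline]:
    """Alternate scan direction line by line: odd-indexed lines reversed.

    With lines sorted by plane offset this places consecutive line endpoints
    near each other, so the inter-line travel jumps stay short.
    """
    return [p.reversed() if i % 2 == 1 else p for i, p in enumerate(polylines)]


def generate_lattice_path(
    mesh: TriangleMesh,
    d: float = 1.0,
    max_step: float = 2.09,
    layers: int = 1,
    layer_offset: Optional[float] = None,
) -> LatticePath:
    """Build the conformal lattice path for one surface patch.

    Parameters
    ----------
    mesh : the surface patch (height field, mm).
    d : interplanar distance = lattice pore pitch (mm).
    max_step : maximum spacing S between consecutive deposit waypoints (mm).
    layers : number of stacked lattice layers.  Layer k is the same path
        with the two plane families swapped on odd k and raised by
        k * ``layer_offset``; ``layer_offset`` is required when layers > 1
        (single-layer default matches deposition directly on the patch).
    """
    if d <= 0 or max_step <= 0:
        raise PathError("d and max_step must be positive")
    if layers < 1:
        raise PathError("layers must be >= 1")
    if layers > 1 and layer_offset is None:
        raise PathError("layer_offset is required when layers > 1")
    mesh.validate()
    bounds = mesh.bounds
    try:
        x_lines = slice_mesh_family(mesh, build_plane_family(bounds, "x", d))
        y_lines = slice_mesh_family(mesh, build_plane_family(bounds, "y", d))
    except SliceError as exc:
        raise PathError(f"mesh too small for any slicing plane: {exc}") from exc
    if not x_lines and not y_lines:
        raise PathError("slicing produced no surface polylines (empty path)")

    def family_pass(lines: Sequence[SurfacePolyline]) -> list[SurfacePolyline]:
        return [resample_polyline(p, max_step) for p in serpentine_order(lines)]

    points: list[PathPoint] = []

    def append_lines(lines: Sequence[SurfacePolyline]) -> None:
        for line in lines:
            for j, pos in enumerate(line.points):
                if j == 0:
                    points.append(PathPoint(pos, "travel"))
                else:
                    points.append(PathPoint(pos, "deposit"))

    for k in range(layers):
        fam_a, fam_b = (x_lines, y_lines) if k % 2 == 0 else (y_lines, x_lines)
        lift = np.array([0.0, 0.0, k * (layer_offset or 0.0)])
        for fam in (fam_a, fam_b):
            lifted = [SurfacePolyline(p.points + lift, p.source_plane) for p in fam]
            append_lines(family_pass(lifted))

    # collapse duplicate consecutive points (a travel of zero length)
    cleaned: list[PathPoint] = []
    for p in points:
        if cleaned and np.linalg.norm(p.position - cleaned[-1].position) < 1e-12:
            continue
        cleaned.append(p)

    return LatticePath(
        points=tuple(cleaned),
        interplanar_distance=float(d),
        max_step=float(max_step),
        n_x_lines=len(x_lines),
        n_y_lines=len(y_lines),
    )


@dataclass(frozen=True)
class PathMetrics:
    total_deposit_length: float
    total_travel_length: float
    n_points: int
    max_deposit_spacing: float
    pore_pitch: Optional[float]


def _line_blocks(path: LatticePath) -> list[np.ndarray]:
    """Split the path into deposit lines at travel points."""
    blocks: list[list[np.ndarray]] = []
    current: list[np.ndarray] = []
    for p in path.points:
        if p.move == "travel":
            if len(current) >= 2:
                blocks.append(np.array(current))
            current = [p.position]
        else:
            current.append(p.position)
    if len(current) >= 2:
        blocks.append(np.array(current))
    return blocks


def path_metrics(path: LatticePath) -> PathMetrics:
    """Length, spacing and pitch summary of a lattice path.

    Pore pitch is the mean spacing between consecutive parallel deposit
    lines measured at mid-span; it is well defined for height-field
    patches, where each deposit line has a constant x (x-family) or
    constant y (y-family) coordinate.
    """
    if len(path.points) == 0:
        raise PathError("empty path has no metrics")
    pos = path.positions
    moves = [p.move for p in path.points]
    deposit_len = travel_len = 0.0
    max_dep = 0.0
    for i in range(1, len(pos)):
        step = float(np.linalg.norm(pos[i] - pos[i - 1]))
        if moves[i] == "deposit":
            deposit_len += step
            max_dep = max(max_dep, step)
        else:
            travel_len += step

    # classify each deposit line by its constant horizontal coordinate
    x_levels, y_levels = [], []
    for block in _line_blocks(path):
        mid = block[len(block) // 2]
        if np.ptp(block[:, 0]) < 1e-6:
            x_levels.append(mid[0])
        elif np.ptp(block[:, 1]) < 1e-6:
            y_levels.append(mid[1])
    pitches = []
    for levels in (x_levels, y_levels):
        if len(levels) >= 2:
            pitches.extend(np.diff(np.sort(np.array(levels))))
    pitch = float(np.mean(pitches)) if pitches else None

    return PathMetrics(
        total_deposit_length=deposit_len,
        total_travel_length=travel_len,
        n_points=len(pos),
        max_deposit_spacing=max_dep,
        pore_pitch=pitch,
    )
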