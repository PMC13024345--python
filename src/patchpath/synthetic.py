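"""Deterministic synthetic surface-patch fixtures.

No public anatomical mesh accompanies the deposition problem this package
addresses, so every downstream stage (slicing, lattice assembly, kinematic
execution) is exercised on generated stand-ins: a spherical cap at the same
footprint scale as a humeral-head patch (~20 mm circular region), a wavy
sinusoidal plate as an irregular-surface stress case, and a flat plate whose
lattice path has an exact planar-grid oracle.

All fixtures are height fields — single-valued z over the build plane —
because a 4-DOF arm holding a vertical nozzle can only deposit on
upward-facing surfaces.  All are exactly reproducible given (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .mesh import TriangleMesh


class FixtureError(ValueError):
    """Invalid fixture specification (geometrically impossible patch)."""


@dataclass(frozen=True)
class PatchSpec:
    """Specification of a synthetic surface patch.

    Parameters
    ----------
    kind : ``spherical_cap`` | ``wavy`` | ``flat_plate``
    cap_diameter : footprint diameter of the spherical cap (mm).
    sphere_radius : radius of the sphere the cap is cut from (mm).
    amplitude, wavelength : sinusoid parameters of the wavy plate (mm).
    extent : (x, y) footprint of plate-type patches (mm).
    resolution : target edge length of the tessellation (mm).
    seed : RNG seed for optional grid jitter (wavy patches only).
    jitter : jitter magnitude as a fraction of ``resolution``; default 0
        (regular grid).
    """

    kind: str = "spherical_cap"
    cap_diameter: float = 20.0
    sphere_radius: float = 25.0
    amplitude: float = 1.0
    wavelength: float = 10.0
    extent: tuple[float, float] = (10.0, 10.0)
    resolution: float = 0.5
    seed: int = 0
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("spherical_cap", "wavy", "flat_plate"):
            raise FixtureError(f"unknown patch kind: {self.kind!r}")
        if self.resolution <= 0:
            raise FixtureError("resolution must be positive")
        if self.kind == "spherical_cap" and self.cap_diameter > 2 * self.sphere_radius:
            raise FixtureError(
                f"cap_diameter {self.cap_diameter} exceeds sphere diameter "
                f"{2 * self.sphere_radius}: no such cap exists"
            )
        if self.kind == "wavy" and self.wavelength <= 0:
            raise FixtureError("wavelength must be positive")


def make_patch(spec: PatchSpec) -> TriangleMesh:
    """Dispatch on ``spec.kind``."""
    if spec.kind == "spherical_cap":
        return make_spherical_cap(spec)
    if spec.kind == "wavy":
        return make_wavy_patch(spec)
    return make_flat_plate(spec)


# -- spherical cap --------------------------------------------------------


def _stitch_rings(inner: np.ndarray, inner_ang: np.ndarray,
                  outer: np.ndarray, outer_ang: np.ndarray) -> list[tuple[int, int, int]]:
    """Triangulate the annulus between two concentric vertex rings.

    Classic two-pointer stitch: always advance the ring whose next vertex
    comes first in angle, producing len(inner)+len(outer) triangles.
    """
    n_i, n_o = len(inner), len(outer)
    faces = []
    i = j = 0
    while i < n_i or j < n_o:
        next_i = inner_ang[i + 1] if i + 1 < n_i else inner_ang[0] + 2 * math.pi
        next_o = outer_ang[j + 1] if j + 1 < n_o else outer_ang[0] + 2 * math.pi
        if j >= n_o or (i < n_i and next_i <= next_o):
            faces.append((inner[i % n_i], outer[j % n_o], inner[(i + 1) % n_i]))
            i += 1
        else:
            faces.append((inner[i % n_i], outer[j % n_o], outer[(j + 1) % n_o]))
            j += 1
    return faces


def make_spherical_cap(spec: PatchSpec) -> TriangleMesh:
    """Spherical-cap patch: apex at z = h (the sagitta), rim at z = 0.

    Every vertex lies exactly on the sphere of radius ``sphere_radius``
    centred at (0, 0, h - R); the projected footprint is the disc of
    diameter ``cap_diameter`` centred on the origin.
    """
    if spec.kind != "spherical_cap":
        raise FixtureError("spec.kind must be 'spherical_cap'")
    R = spec.sphere_radius
    a = spec.cap_diameter / 2.0
    h = R - math.sqrt(R * R - a * a)  # sagitta
    cz = h - R  # sphere centre z

    n_rings = max(1, math.ceil(a / spec.resolution))
    vertices: list[tuple[float, float, float]] = [(0.0, 0.0, h)]
    ring_idx: list[np.ndarray] = [np.array([0])]
    ring_ang: list[np.ndarray] = [np.array([0.0])]
    for k in range(1, n_rings + 1):
        r = a * k / n_rings
        n_pts = max(3, math.ceil(2 * math.pi * r / spec.resolution))
        ang = 2 * math.pi * np.arange(n_pts) / n_pts
        z = cz + math.sqrt(R * R - r * r)
        start = len(vertices)
        vertices.extend(zip(r * np.cos(ang), r * np.sin(ang), np.full(n_pts, z)))
        ring_idx.append(np.arange(start, start + n_pts))
        ring_ang.append(ang)

    faces: list[tuple[int, int, int]] = []
    # apex fan
    first = ring_idx[1]
    for j in range(len(first)):
        faces.append((0, int(first[j]), int(first[(j + 1) % len(first)])))
    for k in range(1, n_rings):
        faces.extend(_stitch_rings(ring_idx[k], ring_ang[k], ring_idx[k + 1], ring_ang[k + 1]))

    mesh = TriangleMesh(np.array(vertices), np.array(faces))
    return _orient_up(mesh)


# -- plate-type patches ---------------------------------------------------


def _grid_plate(spec: PatchSpec, height) -> TriangleMesh:
    ex, ey = spec.extent
    nx = max(1, math.ceil(ex / spec.resolution))
    ny = max(1, math.ceil(ey / spec.resolution))
    xs = np.linspace(0.0, ex, nx + 1)
    ys = np.linspace(0.0, ey, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        dx = rng.uniform(-1, 1, X.shape) * spec.jitter * spec.resolution
        dy = rng.uniform(-1, 1, Y.shape) * spec.jitter * spec.resolution
        dx[0, :] = dx[-1, :] = 0.0
        dx[:, 0] = dx[:, -1] = 0.0
        dy[0, :] = dy[-1, :] = 0.0
        dy[:, 0] = dy[:, -1] = 0.0
        X, Y = X + dx, Y + dy
    Z = height(X, Y)
    vertices = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def vid(i, j):
        return i * (ny + 1) + j

    faces = []
    for i in range(nx):
        for j in range(ny):
            faces.append((vid(i, j), vid(i + 1, j), vid(i + 1, j + 1)))
            faces.append((vid(i, j), vid(i + 1, j + 1), vid(i, j + 1)))
    return _orient_up(TriangleMesh(vertices, np.array(faces)))


def make_wavy_patch(spec: PatchSpec) -> TriangleMesh:
    """Sinusoidal egg-crate plate: z = A sin(2πx/λ) sin(2πy/λ)."""
    if spec.kind != "wavy":
        raise FixtureError("spec.kind must be 'wavy'")
    two_pi_l = 2 * math.pi / spec.wavelength

    def height(x, y):
        return spec.amplitude * np.sin(two_pi_l * x) * np.sin(two_pi_l * y)

    return _grid_plate(spec, height)


def make_flat_plate(spec: Optional[PatchSpec] = None, **kwargs) -> TriangleMesh:
    """Flat rectangular plate at z = 0 (the planar-limit oracle)."""
    if spec is None:
        spec = PatchSpec(kind="flat_plate", **kwargs)
    return _grid_plate(spec, lambda x, y: np.zeros_like(x))


def _orient_up(mesh: TriangleMesh) -> TriangleMesh:
    """Flip any face whose normal points downward (height fields face +z)."""
    flip = mesh.face_normals[:, 2] < 0
    faces = mesh.faces.copy()
    faces[flip] = faces[flip][:, ::-1]
    return TriangleMesh(mesh.vertices, faces, mesh.n_degenerate_removed)
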