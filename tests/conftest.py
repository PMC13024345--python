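"""Shared fixtures and independent geometric oracles.

The point-to-mesh distance oracle below is a brute-force per-triangle
closest-point computation (Ericson's region classification), deliberately
independent of the slicing code it is used to check.
"""

from __future__ import annotations

import numpy as np
import pytest

from patchpath import ArmModel, PatchSpec, make_flat_plate, make_spherical_cap, make_wavy_patch


@pytest.fixture(scope="session")
def flat_plate_10():
    """10 x 10 mm flat plate at z = 0, 0.5 mm tessellation."""
    return make_flat_plate(extent=(10.0, 10.0), resolution=0.5)


@pytest.fixture(scope="session")
def cap_spec():
    return PatchSpec(kind="spherical_cap", cap_diameter=20.0, sphere_radius=25.0,
                     resolution=0.5)


@pytest.fixture(scope="session")
def cap_mesh(cap_spec):
    """Spherical-cap patch at the demonstration scale (D=20, R=25 mm)."""
    return make_spherical_cap(cap_spec)


@pytest.fixture(scope="session")
def wavy_mesh():
    return make_wavy_patch(
        PatchSpec(kind="wavy", extent=(10.0, 10.0), amplitude=1.0, wavelength=10.0,
                  resolution=0.8)
    )


@pytest.fixture(scope="session")
def arm():
    return ArmModel()


def point_triangle_distance(p: np.ndarray, tri: np.ndarray) -> float:
    """Exact distance from a point to one triangle (closest-point regions)."""
    a, b, c = tri
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return float(np.linalg.norm(ap))
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return float(np.linalg.norm(bp))
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        v = d1 / (d1 - d3)
        return float(np.linalg.norm(p - (a + v * ab)))
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return float(np.linalg.norm(cp))
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        w = d2 / (d2 - d6)
        return float(np.linalg.norm(p - (a + w * ac)))
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return float(np.linalg.norm(p - (b + w * (c - b))))
    denom = va + vb + vc
    v, w = vb / denom, vc / denom
    return float(np.linalg.norm(p - (a + ab * v + ac * w)))


def point_to_mesh_distance(points: np.ndarray, mesh) -> np.ndarray:
    """Brute-force min distance of each point to any mesh triangle."""
    tris = mesh.vertices[mesh.faces]
    points = np.atleast_2d(points)
    out = np.empty(len(points))
    centers = tris.mean(axis=1)
    # lower bound dist(p, tri_j) >= |p - center_j| - r_max prunes the scan;
    # r_max must be the global max for the bound to stay valid once sorted
    r_max = np.linalg.norm(tris - centers[:, None, :], axis=2).max()
    for i, p in enumerate(points):
        d_center = np.linalg.norm(centers - p, axis=1)
        best = np.inf
        for j in np.argsort(d_center):
            if d_center[j] - r_max > best:
                break
            best = min(best, point_triangle_distance(p, tris[j]))
        out[i] = best
    return out
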