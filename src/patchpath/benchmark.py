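"""Circular-trajectory spatial-discretization benchmark.

A closed circle of diameter D (default 20 mm) is discretized into N
waypoints.  Executing the waypoint cycle with straight-chord interpolation
produces a polygonal approximation whose radial error is a pure function of
N: every interior chord sample lies inside the circle, so the mean sampled
radius is below D/2 and the spread of sampled radii shrinks as N grows.
The benchmark quantifies both statistics and compares the spread against
the arm's positional repeatability threshold (0.05 mm): once the standard
deviation of the sampled radii falls below the threshold, refining the
discretization further cannot improve the executed trajectory, because the
residual discretization error is already invisible to the hardware.

The arc length per waypoint is S = pi*D/N (the circumference divided by N);
its reciprocal N/(pi*D) is the waypoint density per millimetre of path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .kinematics import ArmModel, execute_path

DEFAULT_N_LIST = (5, 10, 20, 30)


class BenchmarkError(ValueError):
    pass


@dataclass(frozen=True)
class CircleBenchmarkConfig:
    """Circle-benchmark parameters: diameter D, waypoint count N, center,
    interpolation mode and chord sampling density M."""

    N: int
    D: float = 20.0
    center: tuple[float, float, float] = (250.0, 0.0, 50.0)
    mode: str = "cartesian_chord"
    M: int = 200

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise BenchmarkError("diameter must be positive")
        if self.N < 3:
            raise BenchmarkError("need at least 3 waypoints on a circle")
        if self.M < 1:
            raise BenchmarkError("M must be >= 1")


@dataclass(frozen=True)
class TrajectoryStats:
    """Radial statistics of an executed benchmark trajectory (mm)."""

    mean_radius: float
    std_radius: float
    n_samples: int
    rms_from_ideal: float  # RMS deviation from the ideal radius D/2


@dataclass(frozen=True)
class ReportRow:
    N: int
    S: float
    mean_radius: float
    std_radius: float
    below_threshold: bool


@dataclass(frozen=True)
class DiscretizationReport:
    rows: tuple[ReportRow, ...]
    D: float
    eps: float

    def to_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("N,S_mm,mean_radius_mm,std_radius_mm,below_threshold\n")
            for r in self.rows:
                fh.write(
                    f"{r.N},{r.S:.6f},{r.mean_radius:.6f},{r.std_radius:.6f},"
                    f"{str(r.below_threshold).lower()}\n"
                )


def spatial_step(N: int, D: float) -> float:
    """Arc length per waypoint, S = pi*D/N (mm)."""
    if N < 1:
        raise BenchmarkError("N must be >= 1")
    if D <= 0:
        raise BenchmarkError("D must be positive")
    return math.pi * D / N


def discretization_density(N: int, D: float) -> float:
    """Waypoints per millimetre of circumference, N / (pi*D)."""
    return N / (math.pi * D)


def circle_waypoints(config: CircleBenchmarkConfig) -> np.ndarray:
    """N waypoints at uniform angles on the horizontal circle (open list;
    execution closes the cycle back to waypoint 0)."""
    ang = 2 * math.pi * np.arange(config.N) / config.N
    c = np.asarray(config.center, dtype=np.float64)
    R = config.D / 2.0
    return np.column_stack(
        [c[0] + R * np.cos(ang), c[1] + R * np.sin(ang), np.full(config.N, c[2])]
    )


def run_circle_benchmark(arm: ArmModel, config: CircleBenchmarkConfig) -> TrajectoryStats:
    """Execute the closed circle and compute radial statistics.

    The waypoint cycle is closed (the chord from waypoint N-1 back to
    waypoint 0 is included); samples shared between consecutive chords are
    counted once, and the closing sample coincident with waypoint 0 is
    dropped, so every physical point on the executed polygon contributes
    exactly once.  The standard deviation is the sample standard deviation
    (ddof = 1) of the radii about their own mean.
    """
    wp = circle_waypoints(config)
    closed = np.vstack([wp, wp[:1]])
    samples = execute_path(arm, closed, mode=config.mode,
                           samples_per_segment=config.M)
    # last sample returns to waypoint 0, already present as sample 0
    samples = samples[:-1]
    c = np.asarray(config.center, dtype=np.float64)
    radii = np.hypot(samples[:, 0] - c[0], samples[:, 1] - c[1])
    ideal = config.D / 2.0
    return TrajectoryStats(
        mean_radius=float(radii.mean()),
        std_radius=float(radii.std(ddof=1)),
        n_samples=len(radii),
        rms_from_ideal=float(np.sqrt(np.mean((radii - ideal) ** 2))),
    )


def chord_mean_radius(N: int, D: float) -> float:
    """Closed-form mean radius of the continuous uniform-chord polygon.

    For a chord at apothem a = (D/2) cos(pi/N) with half-length
    b = (D/2) sin(pi/N), the mean distance from the center over the chord is
    (1/2b) [ b*sqrt(a^2 + b^2) + a^2 * ln((b + sqrt(a^2 + b^2)) / a) ].
    Used as the independent oracle for the discretized statistics.
    """
    a = (D / 2.0) * math.cos(math.pi / N)
    b = (D / 2.0) * math.sin(math.pi / N)
    s = math.hypot(a, b)  # = D/2
    return (b * s + a * a * math.log((b + s) / a)) / (2 * b)


def discretization_report(
    arm: ArmModel,
    D: float = 20.0,
    N_list: Sequence[int] = DEFAULT_N_LIST,
    mode: str = "cartesian_chord",
    M: int = 200,
    center: tuple[float, float, float] = (250.0, 0.0, 50.0),
) -> DiscretizationReport:
    """One row per discretization density N, against the repeatability eps."""
    if len(N_list) == 0:
        raise BenchmarkError("N_list must be non-empty")
    rows = []
    for N in sorted(N_list):
        cfg = CircleBenchmarkConfig(N=N, D=D, mode=mode, M=M, center=center)
        stats = run_circle_benchmark(arm, cfg)
        rows.append(
            ReportRow(
                N=N,
                S=spatial_step(N, D),
                mean_radius=stats.mean_radius,
                std_radius=stats.std_radius,
                below_threshold=stats.std_radius < arm.repeatability_eps,
            )
        )
    return DiscretizationReport(rows=tuple(rows), D=D, eps=arm.repeatability_eps)
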