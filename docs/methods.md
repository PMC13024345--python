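# Methods

## Problem

Extrusion bioprinting builds scaffolds layer by layer in horizontal planes.
On curved anatomical targets — a humeral head, a cartilage patch — planar
deposition produces stair-step artifacts and poor surface conformity.
`patchpath` implements a non-planar alternative: the deposition path is laid
out directly *on* the triangulated target surface, as a lattice of filaments
in two orthogonal directions, and its spatial discretization is validated
against the kinematics of a small 4-DOF desktop robot arm before anything is
printed.

The pipeline has two halves that meet in one number, the maximum spatial
step **S**:

1. **Geometry.** The surface mesh is intersected with two families of
   parallel vertical planes (normals along x and along y) at interplanar
   distance **d**. Each plane–surface intersection is a contour polyline on
   the surface; ordered, serpentined and concatenated, the two families form
   a conformal lattice whose pores have pitch d. Every polyline is resampled
   so consecutive waypoints are at most S apart.
2. **Kinematics.** A circle benchmark determines how large S may be: a
   circle of diameter D = 20 mm is discretized into N waypoints
   (S = πD/N) and executed by waypoint interpolation. The spread of the
   executed samples' radial distances quantifies the discretization error;
   once it falls below the arm's positional repeatability ε = 0.05 mm,
   refining the path further buys nothing, because the residual geometric
   error is invisible to the hardware.

## Slicing model

Plane placement is deterministic: for a mesh spanning [min, max] along the
family axis, planes sit at min + k·d for k = 1 … ⌊span/d − 10⁻⁹⌋, strictly
inside the bounds. A 10 mm plate at d = 1 mm therefore gets 9 planes per
family; this convention (boundary planes excluded) makes plane and line
counts reproducible.

Per-triangle intersection classifies the three signed vertex distances with
a 10⁻⁹ mm tolerance and a symbolic perturbation: distances within tolerance
of zero count as positive. Consequences, all intentional:

- a triangle coplanar with the slicing plane contributes nothing (its
  neighbours generate the boundary), so no duplicate overlapping segments;
- a plane through a shared mesh edge yields that edge exactly once, from
  the triangle on the negative side;
- a plane touching a single vertex yields a zero-length segment, which is
  suppressed (< 10⁻⁹ mm).

Segments are chained into maximal polylines by endpoint matching at
10⁻⁶ mm (k-d tree + union–find), ordered monotonically along the in-plane
sweep coordinate (y for x-normal planes, x for y-normal planes), and split
at sweep reversals — the split is a generalisation beyond height-field
inputs, where contours are monotone anyway. Only upward-facing triangles
(normal·ẑ > 0) are sliced: a vertically held nozzle cannot deposit on the
underside of a surface.

Resampling subdivides each polyline chord of length L into ⌈L/S⌉ equal
parts. Inserted points lie exactly on the existing polyline (zero added
chord error) and original points are preserved, so resampling can only
refine, never distort.

Tolerances (10⁻⁹ mm predicates, 10⁻⁶ mm chaining) are three to four orders
of magnitude below the 0.05 mm hardware repeatability; they resolve
floating-point coincidence, not physics.

## Lattice assembly

Within each family the scan direction alternates plane by plane
(odd-indexed lines reversed), which never increases — and on parallel lines
strictly decreases — the inter-line travel. Lines are joined by straight
3D travel moves, the shortest vector between the previous end and the next
start; there is no z-hop or surface-following travel. The x family is
deposited first, then the y family, in a single pass. Multi-layer scaffolds
replay the path with the family order swapped on odd layers and a caller-
supplied z lift per layer; no default layer height exists because it is a
material property (filament diameter), not a path property.

## Arm model

The target device class (DOBOT MG400-like) is a base yaw joint θ₁ carrying
a parallelogram-constrained shoulder/elbow pair θ₂, θ₃ and a tool yaw θ₄.
The parallelogram keeps the tool vertical in every configuration, so the
pose is position + yaw:

    r = L₂ sin θ₂ + L₃ cos θ₃ + L₄
    x = r cos θ₁, y = r sin θ₁
    z = L₁ + L₂ cos θ₂ − L₃ sin θ₃
    yaw = θ₁ + θ₄

θ₂ is measured from vertical, θ₃ from horizontal (zero posture: upper arm
upright, forearm horizontal). Inverse kinematics is the analytic planar
two-link solution in the vertical plane through the base axis; the elbow-up
branch is the default (the device's working posture), elbow-down is
available by flag. Reachability requires |L₂−L₃| ≤ √(r²+h²) ≤ L₂+L₃ with
r the horizontal target distance minus L₄ and h = z − L₁. Joint limits are
logged when exceeded but not enforced — these arms are driven inside a
verified central workspace, and hard limit errors would obscure the
geometric analysis. Default link lengths (138, 175, 175, 66 mm) are
desktop-arm-scale configuration values, not manufacturer data; every
benchmark quantity below is link-invariant in its reference mode.

Actuation is ideal: no backlash, compliance, or dynamics. Trajectory quality
is therefore purely the positional deviation of the executed samples from
the analytic ideal path.

## Circle benchmark

`circle_waypoints` places N points at uniform angles on the horizontal
circle; execution closes the cycle (the chord from waypoint N−1 back to
waypoint 0 is included). Two interpolation modes exist:

- **cartesian_chord** — each chord sampled at M+1 uniform points, shared
  endpoints counted once. This is the reference mode: it is pure geometry,
  independent of link lengths (verified by a two-arm invariance test), and
  default M = 200 puts the discrete statistics within 10⁻⁴ mm of the
  continuous chord integral.
- **joint_linear** — IK at each waypoint, linear joint-space interpolation,
  FK back to Cartesian samples; it converges to the chord statistics as N
  grows and is retained for arm-specific studies.

Statistics are computed on the radial distances of all executed samples
from the circle center: the mean radius, and the **sample standard
deviation (ddof = 1) of the radii about their own mean**. The RMS deviation
from the ideal radius D/2 is reported alongside as an alternative error
measure. Reference values from the closed-form chord integral (mean
distance from center over one chord at apothem a = (D/2)cos(π/N),
half-chord b = (D/2)sin(π/N)):

    mean = (1/2b)·[ b√(a²+b²) + a²·ln((b+√(a²+b²))/a) ]

This oracle is implemented separately (`chord_mean_radius`) and used only
in tests, never by the benchmark itself.

With D = 20 mm and M = 200 the benchmark gives (mean, σ in mm):

    N=5: (8.754, 0.578)   N=10: (9.675, 0.146)
    N=20: (9.918, 0.037)  N=30: (9.964, 0.016)

σ at N = 30 rounds to 0.02 mm and is below ε = 0.05 mm; S = πD/30 =
2.094 mm is thus the coarsest validated spatial step, and is the default
`max_step` of the lattice generator. Mean radius and σ are both strictly
monotone in N (mean ↑ toward D/2, σ ↓ toward 0) — chord samples always lie
inside the circle, so mean < D/2 at every finite N.

Note the coarse-N mean radii depend visibly on how the chords are sampled
(uniform-arc weighting vs waypoint-weighted schemes give different means at
N ≤ 20 while agreeing at N = 10 to two decimals); the uniform-chord model
used here is stated exactly so its numbers are reproducible.

## Synthetic fixtures

No anatomical mesh ships with the package; `patchpath.synthetic` generates
deterministic stand-ins at the same footprint scale as a humeral-head
patch:

- **spherical cap** (default: sphere radius 25 mm, footprint diameter
  20 mm, sagitta 2.087 mm) — a polar triangulated grid whose vertices lie
  on the sphere to 10⁻⁹ mm, so surface-membership claims have a closed-form
  check;
- **wavy plate** — z = A·sin(2πx/λ)·sin(2πy/λ), an irregular-surface
  stress case with optional seeded grid jitter;
- **flat plate** — the planar limit, where the lattice must reduce exactly
  to the classic grid infill.

All fixtures are height fields (injective projection onto the build plane)
and exactly reproducible given their spec. What they do **not** emulate:
real segmentation noise, mesh holes and non-manifold junk from CT-derived
STLs, anisotropic tessellation density, or overhanging anatomy. Passing
tests on these fixtures validates the path-generation geometry and the
discretization analysis, not robustness to dirty clinical meshes.

## Parameters and defaults

| parameter | default | unit | meaning |
|---|---|---|---|
| d | 1.0 | mm | interplanar distance = lattice pore pitch |
| S (`max_step`) | 2.09 | mm | max waypoint spacing, from the N = 30 benchmark |
| ε (`repeatability_eps`) | 0.05 | mm | arm positional repeatability |
| D | 20 | mm | benchmark circle diameter |
| M | 200 | — | samples per chord in the benchmark |
| L₁…L₄ | 138, 175, 175, 66 | mm | link lengths (configuration values) |
| resolution | 0.5 | mm | fixture tessellation target edge length |

## Numerical and design choices

- STL is parsed directly (binary: numpy structured records; ASCII: the
  facet/vertex grammar) so truncation errors can name the failing byte
  offset and cleaning is under explicit control: vertices merged at
  10⁻⁹ mm, faces with area ≤ 10⁻¹² mm² dropped and counted. File normals
  are ignored and recomputed from winding. Coordinates are millimetres by
  documented assumption — STL has no unit metadata.
- Degenerate inputs: empty meshes, single-point polylines, unreachable
  waypoints and impossible caps raise typed errors naming the violated
  bound; zero-length travel moves are collapsed.
- Determinism: there is no randomness anywhere in the pipeline except the
  optional fixture jitter, which is seeded. Identical inputs produce
  byte-identical exports.

## Known limitations

- Single-sided deposition only: surfaces must be height fields from above.
- Travel moves are straight lines; on strongly concave patches a travel
  segment could clip the surface (collision checking is out of scope).
- `joint_linear` mode assumes exact joint servoing between IK solutions;
  real controllers blend, accelerate and overshoot.
- The benchmark's problem sizes (M = 200 chord samples, N up to 1000 in
  limit tests) were chosen so the whole analysis runs in seconds on one
  core while the discrete statistics sit within 10⁻⁴ mm of their
  continuous-limit values.
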