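# Methods

This note documents the models, algorithms, parameters and numerical
choices behind `ieloc`, what the synthetic fixtures do and do not emulate,
and the known limitations.

## Coordinates and volumes

All public coordinates are world millimetres in the subject's native
scanner RAS frame; voxel indices are 0-based and continuous. NIfTI affines
follow the usual precedence (sform when its code is nonzero, else qform,
else the pixdim-scaled base), as implemented by nibabel's best-affine rule;
the codes actually used are logged on read. Volumes are never resampled,
reoriented or intensity-normalized: contact detection depends on the CT's
native resolution, and the test suite shows that linear resampling from
0.5 mm to 1 mm voxels makes small rendered contacts undetectable. CT and
MRI-derived inputs (parcellation, surfaces) are assumed co-registered by
external tools before entry; `ieloc` performs no registration.

## Contact refinement

A seeded contact estimate `p` is iteratively replaced by the weighted
centroid of above-threshold voxels within a radius `r` of the current
estimate, with weights `w = max(I − t, 0)` for intensity `I` and threshold
`t`. Clipping at the threshold means background voxels contribute zero
weight and cannot bias the centroid. Iteration stops when the estimate
moves < 0.01 mm or after 10 iterations (symmetric blobs converge in 2–3).
Defaults: `r = 2.0` mm — the same window as trajectory snapping, so a
refined contact is always reproducible from a snap — and threshold = 99.5th
percentile of finite intensities, which isolates metal from tissue and bone
in typical post-implant CT; both are overridable per call, and an absolute
threshold can replace the percentile (the synthetic fixtures, whose
histograms are noise-dominated rather than tissue-dominated, are usually
thresholded absolutely). A constant volume has no meaningful percentile and
raises a detection error. For a symmetric noise-free blob the procedure is
an exact fixed point of the brute-force weighted centroid; the tests verify
agreement to 0.05 mm and idempotence to 0.01 mm.

Cluster detection for candidate listing uses 26-connected components
(metal blooming produces diagonal contiguity at sub-millimetre voxels),
each reported with its intensity-weighted centroid, peak and voxel count.

## Trajectory automation

Both automation modes place one contact per step and snap each prediction
to the CT:

- **Snapping.** Among above-threshold voxels within `search_radius`
  (default 2.0 mm) of the predicted point and farther than
  `exclusion_radius` (default 1.5 mm, about half the common 3–3.5 mm
  contact pitch) from every already-placed contact, the highest-intensity
  voxel is selected; ties break by distance to the prediction, then by flat
  voxel index so results are deterministic. Refinement then runs from the
  selected voxel. The exclusion rule is what prevents two predictions from
  collapsing onto the same density on tightly curved strips.
- **Extrapolation** (seeds = first two contacts): the next prediction is
  `c[k−1] + (c[k−1] − c[k−2])` — the step between the two most recently
  placed contacts — so the march follows the shaft's local direction and
  tracks gradual bends.
- **Interpolation** (seeds = the two end contacts): a forward march where
  each prediction is the current contact plus the remaining straight-line
  vector to the refined far endpoint divided by the number of gaps still to
  fill. Re-aiming at the far endpoint every step combines the local
  stepping rule with continuous correction toward the known terminus, and
  accumulates no error around bends; a strip turning 90° over 8 contacts is
  recovered with RMS error well under 0.1 mm on noise-free-to-moderate-noise
  fixtures. The march runs from one end only; a two-ended variant was
  considered and rejected as it needs a meeting rule that can disagree by a
  full contact on odd counts.
- **Fallback.** If no admissible voxel exists (gap in the CT, ambiguous
  region fully excluded), the geometric prediction itself is used, the
  contact's provenance is set to `geometric-fallback`, and a warning is
  logged — one bad region does not discard a shaft, and the provenance
  column makes the fallback auditable. Failed refinement of the seed
  contacts themselves is fatal, since everything downstream depends on
  them. A purely geometric even-spacing mode exists for the no-CT case.

Contact counts come from the electrode plan; an explicit `n_total` argument
overrides it. In the seeds file, a group with `first` + `second` rows is
extrapolated and one with `first` + `last` rows is interpolated — the seed
roles themselves are the per-group directive.

## Anatomic labeling

The label of a contact is the mode over the 3×3×3 cube of parcellation
voxels centered on its rounded voxel. Neighbours outside the volume are
skipped, not padded, and the tie rule is applied literally: on any shared
maximal count the center voxel's own label is returned, even if that label
is not among the tied maxima (the restricted variant was considered; the
literal rule is simpler and the two differ only in contrived truncated-cube
cases). Contacts outside the volume label as "unknown" with a warning
rather than an error, since strips routinely exit small fixture volumes.
LUTs are whitespace-delimited FreeSurfer color-LUT text; color columns are
ignored.

## Brain-shift correction

Only groups of ECoG type are considered, and among their contacts only
those strictly inside the closed pial envelope, as decided by the
generalized winding number (sum of signed solid angles / 4π > 0.5) — robust
to glancing intersections where ray-parity tests fail on coarse meshes.
Correction is a two-stage procedure:

1. each interior contact is projected to its exact nearest point on the
   triangulated surface (face interior, edge or vertex — not nearest
   vertex);
2. topology regularization minimizes
   `Σᵢ ‖sᵢ − projᵢ‖² + λ Σ₍ᵢⱼ₎ (‖sᵢ − sⱼ‖ − ‖oᵢ − oⱼ‖)²`
   over the shifted positions `s`, with adjacency the 4-neighbourhood
   within a grid (row-major from `grid_dims`) and chain order within a
   strip. The solver is a coordinate-wise fixed-point sweep — each `sᵢ`
   moves to the weighted mean of its projection anchor and the points at
   original distance from each neighbour along the current direction —
   with all points re-projected onto the surface after every sweep, so the
   on-surface constraint holds exactly at every iterate. Iteration stops
   after 100 sweeps or when the largest per-sweep movement falls below 1e-6
   of the coordinate scale.

`λ` (lambda_topo) defaults to 1.0; λ = 0 reduces to pure projection, and
the tests verify the adjacency-distance term is monotone non-increasing in
λ on an interior-grid fixture, with adjacent distances preserved within
25 % at the default. This explicit objective is this package's concrete
operationalization of projection with preserved electrode topology; it is
documented as such, not as bit-identity with any other implementation.
sEEG coordinates are bit-identical before and after; original ECoG
coordinates are always retained alongside the shifted ones.

## Value mapping

For a vertex at Euclidean distance `d` (mm) from an electrode with value
`v`: the contribution is `v · exp(−d · decay_factor / max_radius)`, and no
value is assigned beyond `max_radius`. Defaults `decay_factor = 1.5`,
`max_radius = 1.0` mm. A vertex within radius of several electrodes
averages their decayed contributions with inverse-distance weights
`1/max(d, 1e-6 mm)` — the monotone reading of distance-weighted averaging
consistent with the discrete rule — so the value is a convex combination of
decayed values and its magnitude can never exceed the largest electrode
magnitude. Discrete mode assigns the raw value of the nearest in-radius
electrode, appropriate for categorical data where averaging is meaningless.
Electrodes with unset values are skipped; display thresholding masks
below-threshold electrodes to unset. Distances are measured from the
shifted coordinate when one exists, else the native one — mapped values
should follow the surface position the viewer shows. Time series map frame
by frame, independently.

## Synthetic fixtures

Contacts are rendered as isotropic Gaussian blobs (default σ = 0.6 mm,
peak 1000) on iid normal background noise (default SD 20) in 0.5 mm voxels;
trajectories are straight lines or circular arcs with exact arc-length
spacing. The randomized recovery study draws 8–12 contacts at 3.5 mm pitch,
uniformly random 3D orientation, straight or arced with curvature radius
60–150 mm, and noise SD up to 10 % of blob amplitude, all from one seed.
Label volumes are built from half-spaces and boxes with an auto-generated
LUT; the pial stand-in is a subdivided icosphere; the brain-shift fixture
lays a grid on a spherical cap by the exponential map and pushes it 8 mm
inward (craniotomy-scale shift).

What the fixtures deliberately do not emulate: skull and bone intensity,
beam-hardening/streak artifacts, cylindrical contact geometry and
anisotropic blooming, gyral/sulcal surface geometry, and non-rigid
CT–MRI misalignment. Passing tests therefore demonstrate the correctness
of the algorithms under their stated models (Gaussian-peaked densities,
closed smooth envelope, integer parcellation), not robustness to every
artifact of clinical data; thresholds and search radii may need per-site
tuning on real scans. Fixture sizes in the test and acceptance runs
(96³ voxels at 0.5 mm, icospheres at 2–3 subdivisions, 50-shaft recovery
studies) were chosen as the smallest problems that still exercise every
code path with realistic contact pitch and curvature.

## Degenerate inputs and tie-breaks

Constant volumes raise detection errors; non-invertible affines raise
header errors; empty or open meshes raise topology errors before any
interior test; an all-unset electrode list raises a mapping error. Snapping
ties are resolved (intensity ↓, distance ↑, flat index ↑) so identical
inputs always give identical outputs; every CLI stage writes a provenance
JSON without timestamps, making reruns byte-identical.

## Limitations

- The snapping threshold is global per call; strongly spatially varying
  background (e.g., contacts abutting skull) may need an absolute
  threshold instead of the percentile default.
- The topology penalty preserves pairwise adjacent distances, not angles;
  extreme shifts on coarse meshes can still shear a grid.
- Template-space coordinates are pass-through only; no normalization is
  computed.
- Hemisphere assignment for dual-envelope workflows uses the nearer
  envelope; midline grids should be corrected against a single combined
  envelope.
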