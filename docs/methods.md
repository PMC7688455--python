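# Methods

## Problem and model

External–internal correlation is the standard workaround for tracking a
thoracic or abdominal tumor without continuous X-ray imaging: an externally
observable surrogate signal is mapped to the internal target position
through a model fitted during a calibration session. Classically the
surrogate is the position of a few optical markers glued to the chest;
respivox instead characterizes the motion of the *whole* thoracoabdominal
surface. Per time frame, a depth-camera point cloud of the torso is
cleaned, closed into a watertight point shell, voxelized into a solid
occupancy grid, and summarized by three kinds of features: total volume
`V` (mm³), outer-layer area `S` (mm²), and the coordinates `ψ` of a
locally linear embedding (LLE) of the binary occupancy vectors. The
characterization vector per frame is `Γ = [V, S, ψ₁…ψ_m]ᵀ`; the single
embedding dimension most correlated with the internal motion drives a
phase-split polynomial correlation model

    x_T = Σ_j A_j⁺ r^j   (exhale)      x_T = Σ_j A_j⁻ r^j   (inhale)

with separate coefficient sets per breathing phase because pulmonary
hysteresis makes inhalation and exhalation trace different
external–internal curves. Phases are delimited at the peaks and valleys of
the surrogate; degree N ∈ {1, 2, 3}, default 2 (higher degrees overfit).
The surrogate is z-scored with training statistics before fitting since
embedding coordinates carry no physical scale.

## Synthetic breathing phantom

No deposited dataset exists for this kind of rig, so the package ships a
phantom that generates the study inputs:

- **Torso**: upper half-ellipsoid, half axes `(a, b, c) = (150, 100, 80)` mm
  by default (a compact phantom torso), lying on the z = 0 plane, body axis
  along x. Surface locations are addressed by `(u, v) = (x/a, y/b)`.
- **Sampling**: one rest-state sample of `point_density` (default 4000)
  surface locations on a Fibonacci hemisphere lattice — the quasi-regular
  spacing emulates a structured-light camera's pixel raster. An i.i.d.
  uniform sample would leave super-voxel holes at 5 mm resolution that no
  real sensor raster produces.
- **Breathing**: each point moves along its outward normal by
  `A·a(u,v)·s(t)` with `A = surface_amplitude_max` (default 20 mm, the
  upper end of quiet-breathing abdominal excursion), `a(u,v)` a Gaussian
  bump (width 0.35 in uv units) peaking at `amplitude_center = (0.3, 0)` —
  the abdomen — so markers at different skin sites see different motion
  ranges. The default waveform `s(t) = cos⁴(πt/T)` (T = 4 s) dwells at
  end-exhale as quiet breathing does; a pure sinusoid is selectable.
- **Sensor model**: isotropic Gaussian noise (default σ = 1 mm,
  depth-camera scale) plus a fraction (default 2%) of gross outliers drawn
  uniformly in the 1.5× inflated bounding box of the motion envelope.
- **Tumor**: moves along the body axis by `tumor_amplitude·g(s(t − lag))`,
  default amplitude 10 mm, phase lag 0.3 rad (hysteresis), `g` linear /
  quadratic / cubic.
- **Markers**: evaluated on the analytic noiseless deformation field, then
  optionally noised. The default comparison adds the same 1 mm noise the
  clouds carry, i.e. markers tracked by the same camera rig. This matters
  for interpretation: the phantom's deformation field has a single spatial
  mode, so a *noiseless* marker anywhere with a(u,v) > 0 would be a perfect
  surrogate; the advantage of the whole-surface feature in this phantom
  comes from averaging sensor noise over tens of thousands of voxels,
  whereas in a real torso it additionally comes from multi-mode breathing
  that no single marker can see. Passing tests therefore demonstrate noise
  robustness and correct mechanics, not multi-mode superiority.

The generator is deterministic given the config (seed included); frames at
t and t + T are identical when noise and outliers are disabled.

## Pipeline stages and the choices behind them

**Preprocessing** (fixed order: bilateral → statistical → ROI → MLS).
Bilateral denoising displaces points along their PCA normals by a
spatially/range-weighted neighbor average (σ_s = 5 mm, σ_r = 2 mm,
k = 20). Statistical outlier removal thresholds the mean k-NN distance at
mean + nσ·sd; the pipeline iterates it to convergence at nσ = 5 (classic
sigma clipping) because a single 2σ pass is non-robust both ways: with
gross outliers present they inflate the sd and survive, and without them
the tight lattice sd amputates the legitimately stretched surface over the
inflating abdomen. MLS smoothing projects each point onto a local
degree-2 polynomial patch (radius 10 mm, Gaussian weights of width
radius/2); displacements larger than the fit radius indicate an
ill-conditioned local system and are discarded.

**Watertight closure.** Boundary points are detected by the maximal
angular gap among k tangent-projected neighbors. The op defaults (k = 10,
gap > π/2) suit regular grids; the pipeline uses k = 16 and 0.8π because
among 10 uniformly random neighbor angles the *expected* maximum gap
already exceeds π/2. Candidates are filtered to the xy convex-hull
silhouette (tolerance 15 mm) — interior false positives otherwise spawn
walls with large lever arms — then classified by body-axis quantiles
(0.12, 0.88) into shoulder / waist / abdominal-end runs. The back is the
patch projected onto a plane 50 mm below the waist; the pipeline pins this
plane at the frame-0 level for the whole sequence (physically: the
treatment couch does not breathe; numerically: a per-frame plane crosses
voxel boundaries and toggles the ~10³-voxel back layer between frames).
Walls interpolate each boundary point down to the plane at the voxel
pitch; the full boundary loop is first resampled along its azimuth-ordered
polyline at half the layer spacing, which closes detection gaps and the
junctions between wall classes. Straight drops are the default; the
quarter-arc waist profile (flaring outward along the torso's lateral
curvature) is available as `waist_style="arc"` for visualization, but the
pocket it encloses against the inner curtain seals or opens under sensor
noise and injects bimodal jumps into V and S, so the encoder does not use
it. The projected back is complemented by a 2D-rasterized, hole-filled
floor so the model is closed underneath at any voxel resolution.

**Voxelization.** Cells are half-open, `[origin + i·r, origin + (i+1)·r)`,
with origins snapped to the world lattice so same-resolution grids align.
Solid occupancy = shell voxels ∪ cells unreachable by a 6-connected
exterior flood from a padded corner. Because a one-voxel-thick sampled
surface is not 6-connectivity-tight on steep slopes or where it runs
tangent to a cell boundary, the flood *barrier* (only) is made
conservative: midpoints to the 6 nearest neighbors, one extra layer of
points above and below, and one morphological closing pass. Helper cells
in contact with the exterior flood are discarded from the reported solid,
so analytic shells (a hollow cube, a single point) voxelize exactly.
`V = count·r³` overshoots an analytic volume by about half the one-cell
surface band (≈ S·r/2, e.g. +4.8% for a (100, 80, 60) mm ellipsoid at
2 mm), shrinking linearly with resolution; this bias is inherent to
counting whole shell cells and is shared by all frames, so it cancels out
of the respiratory signal. `S` counts occupied faces adjacent to empty
space. The closure check floods toward an interior seed placed above the
back-plane centroid and reports the leak voxel on failure.

**Template encoding.** Per-frame tight boxes are taken in shared world
lattice coordinates; the template spans their union, anchored at the
union's minimum corner (frames share the fixed back plane, so this equals
the per-axis maxima of the frame box sizes). Frame vectors are linearized
x-fastest (`l = ix + iy·L + iz·L·W`). Anchoring in world coordinates
rather than per-frame box corners preserves the anterior wall's motion —
which *is* the respiratory signal — in the vector representation.

**LLE.** Neighbors by brute-force Euclidean distance (n is a frame count;
a spatial tree degenerates in 10⁵ dimensions), K = 12, d = 10 by default.
Local Gram matrices are regularized by `reg·trace(G)/K` with reg = 10⁻³
(binary rows make G rank-deficient). The embedding is the d bottom
nonzero eigenvectors of `(I − W)ᵀ(I − W)`; the constant eigenvector at
eigenvalue ≈ 0 is discarded, columns are ordered by ascending eigenvalue,
and each column's sign is fixed so its correlation with the frame index is
non-negative, making runs byte-reproducible. Dimension selection computes
|Pearson| of every column against the internal trajectory, warns unless
exactly one exceeds 0.5, and returns the argmax.

**Correlation.** Extrema are found on a 5-frame moving average with a
prominence floor of 20% of the global peak-to-peak; same-kind neighbors
keep the more extreme one so peaks and valleys alternate. Frames from a
peak to the next valley are exhale, valley to peak inhale; ties at an
extremum start the segment beginning there. Evaluation splits the series
chronologically (default 50/50), fits on the first part, and reports
held-out MSE (mm²) plus training Pearson per surrogate.

## Problem sizes

The study-scale configuration is 600 frames (60 s at 10 Hz), 4000 points
per frame, 5 mm voxels (template ≈ 10⁵ cells); one run takes about two
minutes on one core. Replicated comparisons (marker vs reduced feature;
phase-split vs unsplit) use a proportionally scaled phantom — (100, 70,
50) mm torso, 60–120 frames at 5 Hz, 1200–1500 points, 8 mm voxels — so
that 50-replicate suites remain minutes, not hours; the effects being
tested are scale-free.

## Known limitations

- The phantom deforms with a single spatial mode and no cardiac component;
  see the marker note above for what that implies about comparisons.
- The silhouette filter assumes a convex torso footprint in xy.
- The closure machinery targets upward-facing single patches (a lying
  subject seen from above); arbitrary open manifolds are out of scope.
- No out-of-sample LLE extension: the embedding is recomputed per
  sequence, matching the per-session calibration workflow, and no temporal
  forecasting of future tumor positions is attempted.
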