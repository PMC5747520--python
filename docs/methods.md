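# Methods

This note documents the models, conventions and numerical choices behind
`cardiomap`, and what the synthetic-heart validation does and does not
establish about real imaging data.

## Pipeline model

### Synchronization of per-plane movies

Plane-by-plane acquisition of a beating (here: uncoupled, non-contracting)
heart yields movies that each start at an arbitrary cardiac phase.  The
cycle length L (frames) is estimated from the middle plane as the first
significant peak of the frame-mean autocorrelation, refined to the integer
lag maximizing the full-frame lag correlation within ±2 frames (the
frame-mean trace alone is occasionally off by one frame in noise).  A
reference cycle start is drawn by a seeded RNG, and planes are matched
outward in two passes (middle → first, middle → last), each plane against
its already-synchronized neighbor.  Matching scans every candidate start
frame (dense scan) and maximizes the Pearson correlation of the two
L-frame blocks flattened over frames and pixels; ties within 1e-9 break
toward the smallest start.  The chained reference tolerates the gradual
appearance change with depth.  No sub-frame interpolation and no
heart-rate-variability correction are attempted: residual per-plane errors
are at most about one frame and appear downstream as activation-time
jitter between cells of adjacent planes.

### Cells, reference volumes, transients

Nuclei are detected with multi-scale Laplacian-of-Gaussian filtering in
physical units (per-axis sigmas absorb the 0.5/0.5/1 µm voxel
anisotropy; blob radius = σ√3).  Scale-space overlap pruning is kept
permissive; doubled detections are instead removed by an explicit
exclusion radius (default 2 µm, keeping the brighter detection), which
behaves better in densely packed epithelia.  Detector defaults
(`threshold_rel`, scale range) were tuned once on synthetic stacks.
File-based curation (add/delete CSV) replaces interactive editing.

Each cell's reference volume is the set of voxels within 5 voxels
(Euclidean distance in index space, deliberately ignoring anisotropy —
the radius is specified in voxels) of its centroid *and* closer to that
centroid than to any other: Voronoi restriction guarantees each voxel
contributes to at most one cell.  Transients are voxel means per time
point, filtered with the zero-phase circular equivalent of a 4th-order
Butterworth low-pass at 5 Hz — each harmonic of the periodic cycle is
scaled by the squared Butterworth magnitude, which preserves timing
exactly (no phase shift) — then min–max normalized to [0, 1].  Constant
(degenerate) series are zeroed and flagged.

### Activation and rise times

The cardiac cycle has no absolute zero, so each transient is circularly
unwrapped at its global minimum (the diastolic baseline).  Activation time
is the first upward 10%-amplitude crossing after the minimum, linearly
interpolated between frames; rise time is the distance between the 10% and
90% crossings of the same upstroke.  Fleet-wide, activation times are
re-zeroed at the cycle phase following the largest circular gap in the
activation-time distribution — equivalent to zeroing at the earliest cell,
but robust when the arbitrary cycle start bisects the activation sequence.
This requires the total activation span to be shorter than one cycle.
Alignment for display uses a distinct onset definition: first sustained
(2-frame) deviation above a 5% baseline band.

### Midline geometry

The user-traced midline is interpolated by an order-4 (cubic) B-spline —
the minimum smoothness with continuous torsion — and reparameterized to
unit speed by dense arc-length resampling (2048 samples); τ ∈ [0, 1].
Frames follow Frenet–Serret: T = r′/|r′|, N = T′/|T′|, B = T × N, with
curvature |r′ × r″|/|r′|³ and torsion (r′ × r″)·r‴/|r′ × r″|².  Where
curvature falls below 1e-6 µm⁻¹ the normal is undefined; the frame is
continued by rotation-minimizing parallel transport (double-reflection
method) and flagged `transported`, and N-sign continuity is enforced so
frames do not flip across inflection points.  Cell coordinates: τ from the
globally nearest midline point (dense pre-sampling plus bounded local
refinement), z the radial distance, φ = atan2(d·N, d·B) measured from the
binormal toward the normal (config-flippable, since the source convention
is underdetermined).  A cell with a second distance minimum within 1% of
the global one at |Δτ| > 0.05 is flagged ambiguous.  Untwisting and
straightening map each cell to (τL, z sin φ′, z cos φ′) with φ′ the angle
in a torsion-free rotation-minimizing frame; the axis assignment is chosen
so the map is orientation-preserving (a proper rigid motion on already
straight input).

### Conduction network

Topology: per cell, its k = 10 nearest neighbors are centered and
projected onto the top-2 right singular vectors of the neighborhood
(local tangent plane); the 2D Delaunay edges incident to the focal cell
enter the global graph.  A deterministic seeded jitter of 1e-6 of the
bounding-box diagonal — applied to the triangulation coordinates only, and
identical across all local patches — resolves cocircular degeneracies
consistently (a perfect square yields exactly one diagonal).  An optional
absolute edge-length cap prunes trans-lumen shortcuts and the long hull
edges that local patches can produce at domain corners.

Speeds use the neighborhood harmonic form (README): dt is floored at one
frame period (2.5 ms) so simultaneous activation cannot produce infinite
speeds; floored cells are flagged `tie_clamped`, isolated nodes flagged
and left missing.  Shape eigenvalues enter FA and the ellipsoid volume
directly as printed, not as standard deviations (a `use_sqrt_axes` switch
provides the σ-ellipsoid alternative); the volume's units are therefore
µm⁶ under the direct convention — a documented quirk of the printed
formula.  Pacemakers: t_act strictly below the linear-interpolation
0.05 quantile and biological speed strictly below the median (biological
rather than metric speed; switchable).  The 2D conduction map interpolates
speeds linearly on the (τ, φ) rectangle with the point cloud replicated at
φ ± 2π so values are seam-continuous, draws iso-velocity contours at
multiples of 50 cells/s, and reports per-region and inner/outer-curvature
(sign of d·N) medians.

## Synthetic heart

The generator is first-class, tested code; its defaults define the study
conditions for all end-to-end validation.

**Geometry.**  An s-looped midline with torsion (length ≈ 126 µm) and a
radius profile with atrial and ventricular bulges (≈ 14–15 µm) pinched at
the AVC (≈ 7.5 µm).  600 cells are placed on the surface, uniformly per
unit area (density ∝ r(τ)), with 0.4 µm radial jitter and a 3 µm
minimum-separation thinning.  This is a deliberately scaled-down heart —
about half linear scale, with correspondingly small internuclear distances
— chosen so a full two-channel acquisition renders in ~10⁹ voxels·frames
and the whole pipeline runs in minutes; region proportions, looping and
the slow-AVC pattern match the real organ qualitatively.

**Activation.**  Region boundaries at τ = (0.09, 0.42, 0.60, 0.91) split
sinus/atrium/AVC/ventricle/outflow; speeds default to (75, 160, 65, 190,
130) cells/s — AVC slowest, chambers fast, in line with the biological
picture of delay at the atrio-ventricular canal.  The default truth model
is a smooth inflow→outflow front whose longitudinal rate per region is
calibrated on the true cell adjacency (a seam-aware Delaunay triangulation
of the developed tube surface) such that the harmonic-neighborhood speed
measure has the configured value as its regional median: V_region =
v_region × median over region cells of the mean longitudinal neighbor
step.  This makes "configured speed" and "what the estimator measures"
the same quantity by construction, which is what parameter-recovery
testing requires; the residual internal inconsistency (boundary-mixing at
region edges) is ≤ 15% for the narrow AVC and ≤ 10% elsewhere across
seeds.  A literal shortest-path model (per-link delay 1/v, multi-source
Dijkstra from the inflow ring) is available as `activation_model="links"`
for oracle tests; it is *not* estimator-consistent on a 2D tube lattice,
because lateral neighbors share activation times and the harmonic mean
then reads 1.3–1.5× the link speed.  Total activation spans ≈ 405 ms of
the 500 ms cycle, leaving a clear diastolic gap for cyclic unwrapping.
The ground-truth origin ring is defined by applying the pacemaker rule to
the noiseless truth (earliest 5% by true t_act with below-median
configured speed).

**Transients.**  Each cell's waveform is a logistic upstroke whose
continuous 10% and 90% crossings sit exactly at t_act and t_act + rise,
a short plateau, and an exponential decay reaching zero at the next
onset, sampled at 2.5 ms and min–max normalized; construction bias of the
discrete rise time is ~1%.  Default rise times (120, 135, 170, 200,
210) ms increase monotonically from inflow to outflow with a jump at the
AVC.  They were chosen inside the passband of the standard 5 Hz
processing filter (measured smearing ≤ ~3%): with a 500 ms cycle the
filter leaves 120–200 ms kinetics essentially intact, whereas sub-100 ms
rises would be dominated by the filter's own step response and no
processing chain could recover them — the generator emulates the slow
calcium kinetics regime in which the 5 Hz cutoff is a sensible design.
Per-cell rise jitter is 3%.

**Rendering.**  Cells are additive 3D Gaussian blobs (calcium σ = 1.6 µm
on a 100-count baseline with 700-count amplitude; nuclei σ = 1.1 µm in a
separate static channel), sampled at 0.5 µm xy pixels and 1 µm z-steps,
2.5 ms frames, 2.25 cycles per plane.  Each plane starts at an
independent uniform integer phase offset — the worst case the
synchronizer must solve.  Noise is Poisson shot noise plus σ = 3 counts
Gaussian read noise.  All randomness flows from one seed through
independent spawned streams (placement, offsets, per-channel noise), so
identical configs give bit-identical TIFFs.

**What the synthetic validation does not show.**  No tissue motion (the
experimental design uncouples contraction), no optical PSF beyond
Gaussian blobs, no photobleaching, no depth-dependent attenuation or
scattering, no heart-rate variability within an acquisition, and nuclei
are ideal Gaussians rather than textured chromatin.  Passing the suite
therefore demonstrates algorithmic correctness and noise robustness under
this model, not performance on raw microscope data; the detector
thresholds in particular would need re-tuning on real stacks.

## Numerical choices and degenerate inputs

- Quantiles use linear interpolation; pacemaker inequalities are strict
  (deterministic under ties).
- dt floor = one frame period; flagged rather than silent.
- Constant transients → zeroed and flagged; they propagate as NaN metrics,
  never exceptions.
- Straight midlines → fully transported frames seeded from a fixed
  deterministic normal (warning emitted).
- Delaunay degeneracies → consistent seeded jitter, see above.
- Correlation ties in matching → smallest start frame (1e-9 tolerance).
- Frame orthonormality is enforced to machine precision by explicit
  re-orthogonalization; the suite asserts 1e-9.

## Validation scales and observed recovery

The test suite uses three configurations: a tiny heart (60 cells, 150 ms
cycle) for pipeline/determinism tests, a small heart (200 cells, 300 ms
cycle) for sync/detection statistics, and the default heart (600 cells,
500 ms cycle) for acceptance-level parameter recovery; these sizes keep
the full suite within a few minutes on one CPU.  On the default heart the
pipeline recovers 100% of plane offsets within ±1 frame, detects nuclei
with ≈ 98% recall at ≈ 99.8% precision, reproduces per-region median rise
times within ~3% and biological conduction speeds within ~16% (worst
region), identifies the origin ring with precision ≈ 0.96 / recall
≈ 0.83, and recovers τ with RMSE ≈ 0.002.  `scripts/acceptance.py`
recomputes all of these from scratch at any seed.
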