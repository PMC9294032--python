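# Methods

## Imaging model

The C-arm is modeled as a calibrated pinhole camera. World frame: source at
the origin; `x` the source-to-detector (patient AP) axis; `y` patient
mediolateral; `z` patient superior–inferior; detector plane at `x = SDD`
with `u ∥ +y`, `v ∥ +z`; isocenter at `(SDD/2, 0, 0)`. The CT volume center
is placed on the isocenter with its anterior face toward the source,
mirroring the supine-CT / prone-fluoroscopy acquisition convention (the
source sits below the table). Pixel coordinates are 0-based with centers at
integers; the principal point defaults to the detector center.

A pose `(Tx, Ty, Tz, Rx, Ry, Rz)` moves the rigid source+detector pair
relative to the fixed volume: rotation `R = Rz·Ry·Rx` (fixed order, degrees,
about the world axes through the isocenter), then translation in mm. The
Euler order and the rotation center are package conventions — the
underlying physical convention of a given C-arm is not observable from a
single image pair — and are applied identically in simulation and recovery,
so all ground-truth comparisons are self-consistent. Projection is
`p_cam = Rᵀ(p − ic − t) + ic`, `u = u₀ + (SDD·y_cam/x_cam)/Px` (v likewise),
assembled as a rank-3 3×4 matrix.

## DRR rendering

HU → attenuation: `μ = (1000 + HU)/1000 · μ_water`, clamped at 0.
`μ_water` defaults to 0.02 /mm (a typical effective value at diagnostic
energies; configurable — only relative contrast matters for the similarity
metrics, since images are min-max normalized before scoring). Rendering is
exact Siddon traversal — per-voxel intersection lengths, not fixed-step
sampling — with `I₀ = 1`. The primary kernel is numba-compiled and
incremental; an independent vectorized implementation (all plane crossings,
sorted) serves as a cross-checked reference path. Rays missing the volume
return `I₀`; a source inside the volume, or a volume not strictly between
source and detector, is rejected.

Cone-beam note: in-plane rig translation is *not* a uniform image shift
(features shift by `SDD/depth` pixels per mm, depth-dependent); the exact
equivariance the renderer obeys — rig translation by `d` equals volume
translation by `−d` — is what the tests assert.

## Coarse database and similarity search

The preoperative database covers in-plane translations ±50 mm in 2 mm steps
(51² = 2601 poses) at 4 mm detector resolution; the CT is first resampled
to 4 mm as well, so both sides of every comparison live at the coarse
scale. Database images are quantized to 16 bits at build time and cached as
PNGs keyed by a content hash, making the in-memory and reloaded databases
bit-identical and the preoperative build a one-time cost.

Metrics: MI (32 equal-width bins, entropies in bits), GI (Sobel gradients
scaled by pixel spacing, weight `(cos α + 1)/2`, min-of-magnitudes), PSNR,
SSIM (11×11 Gaussian window, σ = 1.5, standard stabilizers), NCC (Pearson).
DRR and radiograph intensities are incommensurate across modalities, so
both images are independently min-max scaled to [0, 255] before scoring;
bin count, gradient operator and window parameters are implementation
choices documented here because no single standard exists. Ties in the
argmax (possible on quantized images) break to the lexicographically
smallest pose. PSNR is the default metric; `rank_metrics` reproduces the
five-way comparison on any ground-truthed case.

## Source-to-detector search

Intensity similarity is unreliable along the viewing axis, so Tx is
localized feature-wise: consecutive intervertebral centroid distances
(label-matched, anatomical order) of the projected CT are compared with
those measured in the radiograph while Tx sweeps from −400 mm (source at
the far point) toward the volume in 10 mm steps, by default up to +200 mm.
The sum of absolute length differences is exactly zero at the true pose for
noiseless landmarks and is unimodal around it on the phantom; the sweep
replaces the manual magnification guess a technician would make.
Correspondence is by vertebral label, never nearest-neighbor; labels
missing from either set are dropped, preserving level order.

## CMA-ES refinement

Fitness is the mean projection distance error over label-matched centroid
pairs, in detector mm; degenerate candidates (a landmark at or behind the
source plane) receive a finite 10⁶ mm penalty so ranking stays defined.
The optimizer is a self-contained (μ/μ_w, λ) CMA-ES with the standard
strategy parameters (log-linear weights, cumulative step-size adaptation,
rank-one + rank-μ covariance update). Protocol defaults: λ = 50, ≤ 2000
evaluations, target mPDE 0; initial steps 10 (mm) for Tx and 3 (mm or
degrees) for the remaining parameters — interpreted as mm for translations
and degrees for rotations — enter through `C(0) = diag(σ₀²)` with unit
global step size. Runs are deterministic given the seed; the best-ever pose
is tracked elitistically, so the reported per-generation trace is
non-increasing. Rotations are optimized even though the simulated gantry is
not rotated, absorbing patient-positioning differences.

With few, nearly collinear centroids the problem has a weakly observable
direction (a rotation about the mediolateral or longitudinal axis traded
against a translation); mPDE converges quickly while individual parameters
can linger in this shallow valley within the evaluation budget. The
phantom's mediolateral curvature (below) bounds this degeneracy; full
parameter recovery to < 1 mm / < 1° needs a ~3× larger budget than the
0.5 mm-mPDE protocol and is verified at 6000 evaluations in the tests.

## Phantom

`generate_spine_phantom` builds a cropped-thoracolumbar analogue: by
default 5 vertebra-like bodies (labels T12–L4) spaced 30 mm along the SI
axis in a 64×64×112-voxel, 2 mm volume. Bodies are ellipsoids (semi-axes
0.8r, r, 0.6r with r = 14 mm) of 700 HU with a 300 HU posterior-process
blob, on a 40 HU soft-tissue elliptic cylinder over −1000 HU air — a
plausible CT palette, exposed as constants since clinical values vary. A
5 mm sinusoidal mediolateral curve plus ±1.5 mm per-vertebra jitter (seeded)
keeps centroids realistically non-collinear, which is also what makes the
6-DOF pose identifiable from them. The stored landmarks are the exact
analytic body centers.

The default C-arm is SDD 1000 mm, 1 mm pixels, 384 mm square detector —
sized so every phantom level stays in view across the coarse grid. Hidden
acquisition poses draw Tx ∈ [−250, −100] mm (magnification ≈ 1.33–1.67,
the clinically typical band), Ty, Tz ∈ [−30, 30] mm and rotations ±2°.
Radiograph perturbation is additive Gaussian noise plus a gamma contrast
change — a stand-in for fluoroscopic contrast/kVp variability, not a
physics model; the default study condition is noiseless, and the 2D
landmarks are always exact projections (annotation error can be injected
separately). What passing tests show is therefore correctness of geometry,
rendering, search and optimization under known ground truth; they do not
certify robustness to scatter, distortion, occluding instruments or
annotation error in clinical images.

## Numerical choices

* Siddon entry voxel via a relative-epsilon midpoint; boundary ties advance
  all crossing axes; segments are exact to ~1e-12 of the chord.
* Database intensities quantized to uint16 at build time (determinism of
  cache round-trips); radiograph files are 16-bit PNG with a JSON sidecar
  carrying the float scale.
* Downsampling is exact block-mean for integer factors (conserves mean
  intensity), linear interpolation otherwise; upsampling is linear.
* PSNR of identical images reports +inf; NCC of a constant image raises
  (inside the search it scores −inf rather than aborting the scan).
* MI is clipped at 0 against histogram round-off; SSIM and NCC are clipped
  to [−1, 1].

## Problem sizes

The shipped study configuration is desk-scale by design: 2 mm CT voxels,
4 mm coarse resolution, 2601-entry database, 5 landmarks, 2000-evaluation
refinement, 10-seed repetition. These sizes make the full pipeline run in
seconds-to-minutes while exercising every stage at the protocol's stated
grid, steps and optimizer settings.

## Known limitations

* Rigid, whole-column registration only: no per-vertebra or deformable
  refinement, no biplane fusion.
* Monochromatic attenuation; no scatter, beam hardening, veiling glare or
  pincushion distortion.
* The phantom is analytic, not anatomical; metric rankings measured on it
  need not transfer to clinical image quality.
* Out-of-plane parameters are weakly determined by near-collinear
  landmarks (see the refinement section); reported mPDE can be small while
  Tx/rotations retain a few mm/degrees of error along the degenerate
  direction.
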