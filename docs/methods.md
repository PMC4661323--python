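# Methods

## Fiber-geometry model

A white-matter voxel is modeled as parallel annular cylinders seen in
cross-section: fiber *j* has outer radius R_O,j and microscopic g-ratio
g_j = R_I,j / R_O,j. The module stores an explicit fiber list rather than
binned radius/g probability distributions — each stored fiber is one draw,
so probability-weighted expectations reduce to plain sums and every
identity holds exactly per realization, not just in expectation. Fibers
are constrained only by the aggregate packing bound Σ π R_O,j² ≤ A (and,
for sampled populations with a target FVF, by the hexagonal circle-packing
ceiling π/√12 ≈ 0.9069); no spatial placement is modeled because none of
the volume-fraction quantities depend on it.

From the list, FVF = Σ π R_O²/A, MVF = Σ π R_O²(1 − g²)/A, EVF = 1 − FVF,
and the aggregate ("MR") g-ratio is g = √(1 − MVF/FVF). Algebraically this
equals the fiber-area-weighted RMS of the g_j, which the package exposes as
an independent code path; the two are tested to agree to 1e-12 relative on
random populations. For a constant-g population the aggregate equals the
microscopic mean; for any non-degenerate distribution the RMS form exceeds
the area-weighted mean (Jensen), and an unmyelinated pool (g = 1) pulls the
aggregate above the myelinated pool's g — the directionality users should
keep in mind when interpreting maps.

Conduction velocity is represented by Rushton's factor f(g) = g·√(ln(1/g))
(velocity at fixed outer diameter ∝ f), maximal at g = 1/√e ≈ 0.607.
Hodgkin's alternative analysis predicts a steeper penalty for deviations
from the optimum; no closed form is adopted for it here, so only the
Rushton factor is implemented.

## MPM fitting

The spoiled-FLASH rational approximation S = A·α·R1·TR/(α²/2 + R1·TR) (α
the flip angle in radians) is used both as the phantom's forward model and
as the fit's inversion target. The PDw/T1w pair (5° and 29° at TR =
25.25 ms in the emulated protocol) is solved in closed form for R1 and the
apparent amplitude A; the MTw equation (9°, TR = 29.25 ms, with the
per-excitation saturation δ added to the denominator) is then solved for δ,
reported ×100 in percent units. All three inversions are algebraically
exact under the model — verified symbolically during development — so the
round-trip tests assert near machine precision.

Practical choices:

* Echoes are averaged (first 6 of 8, configurable) before fitting. A
  voxel-wise T2* echo decay common to the three weightings multiplies all
  three averaged signals by the same factor and cancels exactly in R1 and
  MT; only A absorbs it (hence "apparent").
* Nominal flip angles are used; B1+ inhomogeneity correction is out of
  scope.
* Negative MT-saturation voxels are flagged (`negative_mt`), never clipped,
  so downstream stages see the error rather than a silently sanitized map.
* Fitting runs everywhere; masking is a downstream concern.

## Diffusion fitting and the fiber-density proxy

The tensor is fit log-linearly with weighted least squares: an OLS pass,
then one reweighting with weights equal to the squared predicted signals.
Non-positive signals get zero weight; voxels with fewer than 7 usable
measurements are invalid. The low-b volumes (b = 100 s/mm²) enter the
design matrix with their true b-value — they are diffusion-weighted, not
b = 0. Negative eigenvalues are flagged and excluded from the density
proxy, not clipped.

The fiber-density (FVF-proxy) map is Westin's linear-anisotropy coefficient
c_l = (λ1 − λ2)/(λ1 + λ2 + λ3), clamped at zero and divided by its
white-matter-mask mean, so the mask mean is exactly 1. A genuine
fiber-conservation (tract-fiber-density) solution would be preferable on
real data; it is accepted as an external NIfTI input
(`load_external_density`) on the same mean-1 convention. Fiber density from
diffusion data is in any case only defined up to a per-subject global
factor, and both that factor and the proxy's overall scale are absorbed by
the g-ratio calibration constant α, so the choice of proxy changes spatial
weighting but not the calibration logic. The proxy is a ratio of
eigenvalues, hence invariant to global signal scaling and to global
diffusivity scaling.

## Calibration and the g map

α is solved on a reference ROI so that the ROI statistic of
√(1 − α·MT/density) equals the anchor g (default 0.7, the ex-vivo
splenium value). The default statistic is the mean of voxel-wise g
("mean-of-g"); forming g from ROI-mean MT and density ("ratio-of-means")
is selectable. The mean-of-g statistic is strictly decreasing in α on
(0, α_max], where α_max = min(density/MT) over the ROI keeps every radicand
non-negative, so Brent root-finding on that bracket is guaranteed the
unique solution (tolerance 1e-10 on α). Calibration uses a single subject
and the resulting α is applied to the whole cohort, mirroring common
practice; the calibration subject is a configuration choice.

The g map is computed on the diffusion grid (the coarser of the two), with
the MT map resampled down by trilinear interpolation through world space.
Voxels with non-positive density or α·MT/density > 1 are masked invalid —
not clipped to [0, 1] — because such voxels are precisely the signature of
MT/diffusion misalignment and should stay visible.

Susceptibility distortion is modeled as a 1-D displacement along the
phase-encode axis with linear interpolation and optional Jacobian intensity
modulation; applying the negated field is the first-order inverse, exact
for spatially constant displacements. The shipped demonstration applies a
constant two-voxel shift to the diffusion data, which produces invalid /
g ≈ 1 rims at structure edges in the uncorrected map; the inverse
correction removes ≥ 90% of them in the regression test.

## Group statistics

Voxel-wise cohort mean, sample SD (ddof = 1) and CoV = SD/mean are computed
over subjects with valid voxels (≥ 2 required). Reliability masking uses
strict CoV < 0.3 by default; the atlas threshold for tract ROIs is
prob ≥ 0.5; both conventions are configurable, and tract ROIs under 100
voxels are flagged for exclusion. The corpus-callosum parcellation splits
the mask's anterior–posterior world-mm extent (anterior axis read from the
affine) into equal-width intervals — equidistant in millimetres, not voxel
counts. ROI tables carry per-subject within-ROI means and SDs; the group
summary reports the mean of subject means, the between-subject SD of those
means, and the group mean of within-ROI SDs (the convention used when
comparing against ex-vivo samples, where the spread is within-sample).
Contrasts are a one-way ANOVA on subject-level tract means plus one-sided
two-sample t-tests of each tract against a reference tract at an
uncorrected 0.05 threshold; MT–density association is the per-ROI Pearson
correlation of subject-mean values.

## The synthetic phantom

Geometry: a midline corpus-callosum-like arc spanning the
anterior–posterior axis with thickened ends (genu/splenium bulges) plus two
lateral box "tracts", all defined in world coordinates and rendered on each
grid by voxel-center membership; structures are disjoint. Default ground
truth: CC FVF 0.65 / g 0.70, tract A 0.55 / 0.72, tract B 0.50 / 0.62 —
g values inside the ex-vivo range, with the splenium-like region at the
0.7 calibration anchor, and MVF = FVF·(1 − g²) by construction. The
white-matter mask is the union of per-structure one-voxel erosions on the
diffusion grid, so it excludes boundary voxels where rendering and MT
resampling blend structures.

Forward models mirror the fitting stages exactly: MT_true = κ·MVF with
κ = 6 p.u. per unit MVF (white matter lands near 2 p.u., the conventional
scale), fed through the FLASH equations with T2* decay (40 s⁻¹ in WM,
25 s⁻¹ background) over 8 echoes at 2.37 ms spacing; raw fiber density is
β·FVF with β = 0.6, realized as an axially symmetric tensor with λ1 =
1.7×10⁻³ mm²/s and λ2 = λ3 solved so c_l equals the raw density (the
background is isotropic at 0.9×10⁻³). κ and β are free synthetic scales —
never biological constants — and cancel through α. Diffusion directions are
a deterministic Fibonacci sphere (60 at b = 1000 plus 6 at b = 100 s/mm²).

Noise is Rician (magnitude of complex Gaussian), referenced to the mean
white-matter signal per modality; defaults SNR 50 (MPM) and 20 (dMRI).
Between-subject variation perturbs each structure's g and FVF per subject
(default SD 0.02 each). Seeds split hierarchically (cohort → subject →
draws/MPM-noise/dMRI-noise), so cohorts are bit-reproducible.

What the phantom does *not* emulate: realistic anatomy or partial-volume
mixtures, crossing fibers (each voxel is a single tensor, so the
linear-anisotropy proxy is exact by construction — on real data it is not),
eddy currents, motion, k-space artifacts, or spatially varying receive
fields. Passing recovery tests therefore demonstrates the correctness of
the estimation chain under its own assumptions, not robustness to
real-data violations of them.

## Known limitations and numerical choices

* **Per-subject density normalization vs a single α.** The density map is
  normalized to WM-mask mean 1 per subject, while α is calibrated on one
  subject and shared. If subjects genuinely differ in mean FVF, that
  difference is removed by the normalization and the shared α is exactly
  right only for the calibration subject — a structural property of the
  method (global group differences are invisible to a per-subject
  normalized density), not an implementation artifact. Consequently exact
  end-to-end recovery is only defined for a cohort without between-subject
  FVF variation; the noiseless recovery test uses such a cohort, and the
  noisy test (default between-subject SDs, SNR 20) bounds the median error
  instead.
* Problem sizes in tests and the acceptance script use reduced grids
  (typically 24³ diffusion voxels at 2.3 mm with MPM at 1.15 mm, i.e. half
  the diffusion voxel; the default 32³/0.8 mm phantom where ROI-size
  conventions matter) and 2–3 simulated subjects, which keeps the full
  suite fast while exercising every code path at realistic voxel counts
  per structure. Purely statistical criteria (CoV sampling at n = 37,
  ANOVA type-I error over 1000 replicates) draw scalar maps directly
  rather than re-simulating signals.
* Volumes are float32 on disk, float64 in memory; affines follow RAS+ with
  0-based voxel indices; resampling is trilinear with NaN propagation and
  out-of-field voxels set invalid.
* Degenerate inputs are rejected loudly: empty populations/ROIs/masks,
  singular affines, fibers overflowing the voxel, infeasible calibration
  brackets, zero-variance statistical inputs.
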