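# gratio

Whole-brain MR g-ratio mapping from magnetization-transfer saturation and
single-shell diffusion MRI — together with the fiber-geometry theory behind
it and a fully synthetic multi-subject phantom, so the entire pipeline is
testable without any real scanner data.

## The problem and the model

The g-ratio of a myelinated nerve fiber is the ratio of its inner (axonal)
to outer (axon + myelin) radius. It governs conduction velocity — Rushton's
classical analysis gives velocity ∝ g·√(ln(1/g)) at fixed outer diameter,
maximal at g = 1/√e ≈ 0.6 — and it changes in de- and re-myelinating
disease, which makes a non-invasive voxel-wise map of it a valuable
microstructural biomarker.

MRI cannot resolve single fibers, but it can estimate the myelin volume
fraction (MVF) and the fiber volume fraction (FVF) of a voxel. For a bundle
of parallel annular fibers,

    g_MR = √(1 − MVF / FVF),

and when g varies between fibers, g_MR equals the fiber-area-weighted RMS
of the microscopic g-ratios. Substituting imaging proxies — MT saturation
(from a multi-echo FLASH multi-parameter-mapping protocol) for MVF, and a
diffusion-derived fiber-density map for FVF — the voxel-wise map becomes

    g = √(1 − α · MT / density),

with a single scaling constant α absorbing both proxies' unknown global
factors. α is calibrated once per study by forcing the mean g of a reference
region (the splenium of the corpus callosum) to the ex-vivo literature value
g = 0.7, then held fixed for every subject.

The package implements, as separately usable modules:

| module | contents |
| --- | --- |
| `gratio.microsim` | explicit fiber populations, FVF/MVF summation, mean and area-weighted-RMS g, the √(1 − MVF/FVF) identity, Rushton's conduction-velocity factor |
| `gratio.mpm_fit` | MT-saturation / R1 / amplitude maps from the PDw/T1w/MTw FLASH triplet (echo averaging + exact rational-approximation inversion) |
| `gratio.dwi_fit` | weighted-least-squares tensor fit, FA/MD/AD/RD, the linear-anisotropy fiber-density proxy with per-subject normalization, external density-map loading |
| `gratio.gratio_map` | grid resampling, phase-encode displacement warps, α calibration, the calibrated g map with its validity mask |
| `gratio.group_stats` | voxel-wise cohort mean/SD/CoV, CoV < 0.3 reliability masking, WM histograms, 8-interval corpus-callosum parcellation, tract ROIs, ANOVA + post-hoc contrasts, MT–density correlations |
| `gratio.synthetic_data` | the forward-simulated phantom cohort (FLASH + tensor signals, Rician noise, between-subject variation, optional susceptibility-like displacement) |
| `gratio.io` / `gratio.config` / `gratio.pipeline` / `gratio.cli` | NIfTI and FSL bvals/bvecs I/O, validated JSON run configs, the pipeline driver and the `gratio` command line |

Voxels where the model breaks down (density ≤ 0 or α·MT/density > 1) are
masked invalid rather than clipped — they are diagnostic of misregistration
between the MT and diffusion data, most prominently EPI susceptibility
distortion, which the package can simulate and correct to first order.

## Worked example

Simulate a small three-subject cohort at Rician SNR 20, fit MT and
fiber-density maps, calibrate α on the first subject's splenium-like ROI,
and compare the g maps to the phantom's ground truth:

```python
import numpy as np
from gratio.synthetic_data import PhantomSpec, generate_cohort, make_reference_roi
from gratio.pipeline import process_subject
from gratio.gratio_map import calibrate_alpha, compute_g_map

spec = PhantomSpec(n_subjects=3, seed=7, dmri_shape=(24, 24, 24), mpm_voxel=1.15)
cohort = generate_cohort(spec)
results = [process_subject(s) for s in cohort]

roi = make_reference_roi(cohort[0])
record = calibrate_alpha(results[0].mt_dmri, results[0].density, roi, g_reference=0.7)
print(f"alpha = {record.alpha:.4f}  (ROI mean g = {record.achieved:.6f}, {record.n_roi_voxels} voxels)")

for sub, res in zip(cohort, results):
    g = compute_g_map(res.mt_dmri, res.density, record)
    wm = sub.wm_mask
    err = np.abs(g.g_map - sub.truth["g"])[wm]
    print(f"{sub.subject_id}: WM mean g = {np.nanmean(g.g_map[wm]):.3f}, "
          f"median |g - g_true| = {np.nanmedian(err):.4f}")
```

Output:

```
alpha = 0.2862  (ROI mean g = 0.700000, 8 voxels)
sub-00: WM mean g = 0.679, median |g - g_true| = 0.0179
sub-01: WM mean g = 0.695, median |g - g_true| = 0.0171
sub-02: WM mean g = 0.714, median |g - g_true| = 0.0239
```

The calibration pins the reference ROI's mean g at 0.7 exactly; with noise
and between-subject variation switched off the whole-map error drops to
machine precision, so the residual ~0.02 here is the noise floor at SNR 20.
(The numeric value of α depends on the phantom's MT and density scales; only
the product α·MT/density is meaningful.)

The same chain is available from the shell:

```bash
gratio run --config run.json --out-dir out/   # simulate → fit → calibrate → map → group
gratio simulate --out-dir sim/ --seed 2       # phantom volumes + ground truth on disk
gratio fit-mpm --pdw sim/sub-00/pdw.nii.gz --t1w ... --mtw ... --out-dir maps/
```

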