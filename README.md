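# lesionsr

Lesion-focused CT image super-resolution with a cycle-consistent GAN, and
the radiomics methodology for asking whether super-resolution makes texture
biomarkers *more robust* — or less.

Radiomic texture features are computed from small regions of interest and
are notoriously sensitive to processing choices, in particular the number
of gray levels N_g used to quantize the ROI before building texture
matrices. This package implements the full chain needed to study that
sensitivity on CT lesions:

* **Degradation pipeline** — HU windowing to [-100, 400], normalisation,
  and paired LR/HR patch construction (noise sd 0.25, 8x8 Gaussian blur
  sigma 1.6, 2x down/nearest-up on a common grid).
* **Super-resolution GAN** — two generators G: LR→HR, F: HR→LR and two
  discriminators trained on the four-term objective
  `L_Adv(D_HR,G) + L_Adv(D_LR,F) + λ1 L_Cyc + λ2 L_IDT + λ3 L_JST`
  (λ = 1, 0.5, 1e-5), with spatial pyramid pooling in the discriminators
  so lesion patches of any size can train one network. Runs on a small
  numpy autodiff engine (`lesionsr.nn`) — no deep-learning framework
  required.
* **Evaluation** — PSNR/SSIM, a Catmull-Rom bicubic baseline, Mann-Whitney
  pairwise tests with Benjamini-Hochberg correction.
* **Radiomics** — 75 3D texture features (GLCM 24, GLDM 14, GLRLM 16,
  GLSZM 16, NGTDM 5), fixed-bin-count quantization over
  N_g ∈ {8, 16, 32, 64, 128, 256}, no resampling, no filters.
* **Robustness** — per-feature ICC(3,1) = (MS_R − MS_E)/(MS_R + (k−1) MS_E)
  across rebinnings (k = 6) or morphological contour perturbations
  (k = 3: original/opened/closed, radius-1 ball), robustness bands
  (Excellent means ICC > 0.9), optimal-bin selection, and PCA-based
  feature importance (quadrature sum of correlation-matrix loadings over
  the first three PCs).
* **Phantoms** — synthetic HU volumes with textured spherical lesions and
  cohorts with a controlled between/within variance split, so every stage
  is testable without clinical data.

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

```python
import numpy as np
from lesionsr.phantom import PhantomSpec, CohortSpec, make_cohort
from lesionsr.radiomics import build_table
from lesionsr.robustness import icc_table, perturb_roi, select_optimal_bins

template = PhantomSpec(shape=(16, 48, 48), lesion_radius_vox=6.0, seed=0)
cohort, meta = make_cohort(CohortSpec(n_subjects=6, template=template, seed=0))
volumes = [reps[0] for reps in cohort]

versions = {name: (lambda m, _n=name: perturb_roi(m)[_n])
            for name in ("original", "opened", "closed")}
table = build_table(volumes, bins=(8, 16, 32, 64), roi_versions=versions)

best, summary = select_optimal_bins(table)
print(summary.to_string(index=False))
print("optimal bins:", best)

icc = icc_table(table, mode="bins")
print(icc.sort_values("icc", ascending=False).head(3)[["feature", "icc", "robustness"]]
      .to_string(index=False))
```

Output:

```
 n_bins  n_excellent
      8           71
     16           74
     32           75
     64           75
optimal bins: 32
        feature      icc robustness
      GLCM_Idmn 0.999080  Excellent
GLCM_SumEntropy 0.998365  Excellent
       GLCM_Idn 0.997563  Excellent
```

The per-bin `n_excellent` column counts features whose ICC(3,1) across the
three contour versions exceeds 0.9 — the bin setting with the most such
features (ties broken toward the fewest bins) is selected, here 32. On
these clean phantoms contour perturbation barely moves most features,
hence the high counts; noisier cohorts spread the settings apart. The
`icc` column in the second table is each feature's ICC(3,1) across the
bin settings on the original contours: values near 1 mean rebinning
barely moves the feature relative to between-subject differences.

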