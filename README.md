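# radstab

**Robustness of CT radiomic features under noise, voxel-size and
segmentation perturbations.**

Radiomic features — quantitative descriptors of grey-level statistics and
texture inside a region of interest — are only clinically useful if they
survive the ordinary variability of CT imaging: scan noise, heterogeneous
voxel sizes that force resampling, and imperfect ROI contours.  `radstab`
implements a complete reproducibility pipeline for renal-CT-like images:

1. **Synthetic cohort** — CT phantoms with a heterogeneous tumour-like ROI
   and a smoother kidney-like ROI, matching realistic acquisition
   statistics (in-plane spacing 0.541–0.957 mm, 5 mm slices, noise
   σ ∈ [2.9, 5.9] HU);
2. **Interpolation-kernel selection** — linear vs Akima spline vs Lanczos
   windowed sinc, ranked by the EME-IQ local-contrast score
   (block mean of 20·log₁₀(Bmax/Bmin));
3. **Perturbations** — 29 scenarios from three families: additive white
   Gaussian noise at the image's own estimated σ (**N**), 15 voxel-size
   combinations of three in-plane spacings × slice spacings 1–5 mm (**V**),
   and morphological ROI dilation/erosion to exact volume changes of
   +10/−10/−15/−20 % (**R**);
4. **Features** — 13 first-order statistics and 19 grey-level co-occurrence
   (GLCM) texture features, in 2D (4 directions, per-slice, averaged) and 3D
   (13 directions), at distances δ ∈ {1, 3, 5, 7, 9}, after 2.5 % tail
   trimming and 32-level quantization — 108 canonical feature ids;
5. **Robustness** — per (feature, scenario), the one-way intraclass
   correlation ICC(1,1) = (MSB − MSW)/(MSB + (k−1)·MSW) with its exact
   F-pivot 95 % CI; a feature is *robust* (r) if the CI lower bound ≥ 0.90,
   *non-robust* (nr) if the upper bound < 0.90, *indeterminate* (i)
   otherwise — plus cross-distance redundancy (Pearson ρ, ANOVA).

It is aimed at quantitative-imaging researchers who want a tested,
seed-reproducible reference implementation of this kind of robustness study,
with every numerical convention documented (see `docs/methods.md`).

## Worked example

```python
import numpy as np
from radstab import (AcquisitionSpec, GLCMConfig, MeasurementMatrix,
                     add_awgn, extract_all, generate_case, icc_1_1)

spec = AcquisitionSpec()                      # study-like acquisition stats
vol, tumour, kidney = generate_case(spec, seed=5)
print(vol.voxels.shape, vol.spacing)

feats = extract_all(vol, tumour, GLCMConfig())
print(round(feats["FO:m"], 2), round(feats["GLCM2D:entro:d1"], 3))

# ICC of the ROI mean under re-noising, across a tiny cohort
rows = []
for i in range(10):
    v, t, _ = generate_case(spec, seed=100 + i)
    noisy = add_awgn(v, 4.0, seed=i)
    rows.append([extract_all(v, t)["FO:m"], extract_all(noisy, t)["FO:m"]])
res = icc_1_1(MeasurementMatrix(np.array(rows)))
print(round(res.icc, 4), res.label)
```

prints

```
(10, 88, 88) (0.8758812162780781, 0.8758812162780781, 5.0)
83.55 7.91
0.9999 r
```

— a 10-slice volume with ~0.88 mm voxels, a tumour ROI with mean 83.55 HU
and 2D co-occurrence entropy 7.91 bits at distance 1, and an ICC of 0.9999
(CI entirely above 0.90, hence robust): the ROI mean is essentially immune
to re-noising at scan level, as expected for a spatial average.

## Analysis drivers

The study itself is a sequence of thin scripts over the library:

```bash
python analysis/01_simulate_cohort.py        # 20 cases -> scratch/cohort
python analysis/02_rank_interpolators.py     # EME-IQ kernel ranking
python analysis/03_extract_features.py       # 170k-row tidy feature table
python analysis/04_classify_robustness.py    # ICC grid + r/nr/i summaries
python analysis/05_distance_redundancy.py    # Pearson/ANOVA across delta
```

Each writes its tables under `results/`.  A `radstab` CLI
(`radstab generate | rank-interp | robustness | run`) wraps the same
functions for ad-hoc use.

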