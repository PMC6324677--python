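# dcehabitat

Habitat analysis of prostate DCE-MRI for discriminating clinically
significant prostate cancer.

Multi-parametric prostate MRI includes a dynamic contrast-enhanced (DCE)
series — a 4-D acquisition in which every voxel traces a time-activity
curve after contrast injection — and an apparent diffusion coefficient
(ADC) map. This package implements a semi-quantitative analysis chain for
radiologists' findings confirmed by targeted biopsy: it localises a
*wash-in-slope habitat* (an intra- plus peritumoral subregion of high
contrast uptake rate) around each biopsy site, summarises its perfusion
curve with seven descriptors, adds ADC radiomics of the same region, and
asks how well those descriptors separate clinically significant
(Gleason ≥ 7) from insignificant (Gleason 6) lesions under leave-one-out
and cross-cohort validation. A synthetic mpMRI cohort generator provides
fully reproducible data with known ground truth.

## The model

Each enhancement curve is fitted with a five-parameter bi-exponential
model

```
s(t) = s0                                               t ≤ t0
s(t) = s0 + A · (e^{−k_out (t−t0)} − e^{−k_in (t−t0)})  t > t0
```

with baseline `s0`, start of enhancement `t0`, wash-in rate `k_in` and
wash-out rate `k_out` (`k_in > k_out`). The curve peaks at the analytic
time-to-peak `τ = ln(k_in/k_out)/(k_in − k_out)` with plateau
`s_m = s(t0+τ)`. Seven descriptors follow:

| feature | definition |
|---------|------------|
| `sp`    | peak enhancement, `s_m − s0` |
| `tau`   | time-to-peak τ (s) |
| `wi`    | wash-in slope, `sp / τ` |
| `wo`    | wash-out slope, mean fitted slope from the peak to `t0`+270 s |
| `AUCi`  | area under the fitted, baseline-subtracted curve over [`t0`, `t0`+60 s] |
| `AUCf`  | same over [`t0`+240 s, `t0`+270 s] |
| `mio`   | slope product, `wi · wo` |

The habitat is built per biopsy: a 15 mm sphere around the biopsy point
(absorbing TRUS/MRI fusion error) is clipped to the prostate and to the
zone — peripheral or transition — holding the larger share of the lesion
contour; within it, voxels at or above the 75th percentile of the
voxel-wise `wi` map form the habitat, whose mean curve is refitted for the
descriptors above. ADC features (histogram-gradient grey levels,
intensity-volume-fraction differences, voxel-face surface area, principal
axis lengths, first-order statistics) are computed on the z-scored ADC map
over the same voxels. Classification uses shallow decision trees with
SMOTE balancing to exact class parity, leave-one-out (balanced inside each
training fold) or train-on-one-cohort/test-on-the-other validation,
exhaustive single/pair/quadruple feature search, paired DeLong AUC
comparison and Benjamini–Hochberg FDR correction.

## Worked example

```python
import numpy as np
from dcehabitat import (BiExpFit, TimeActivityCurve, model_curve, fit_curve,
                        extract_features)

times = np.arange(50) * 7.0                      # 7 s frames, ~6 min scan
truth = BiExpFit(s0=0.1, A=1.2, t0=30.0, k_in=0.10, k_out=0.006)
rng = np.random.default_rng(0)
values = model_curve(truth, times) + rng.normal(0, 0.02, times.size)

fit = fit_curve(TimeActivityCurve(times=times, values=values))
feats = extract_features(fit)
print(f"t0 = {fit.t0:.1f} s   tau = {feats.tau:.1f} s   sp = {feats.sp:.3f}")
print(f"wi = {feats.wi:.4f} /s   wo = {feats.wo:.5f} /s   mio = {feats.mio:.2e}")
print(f"AUCi = {feats.auci:.1f}   AUCf = {feats.aucf:.1f}   "
      f"residual = {fit.residual_pct:.1f}%")
```

prints

```
t0 = 30.5 s   tau = 27.1 s   sp = 0.933
wi = 0.0344 /s   wo = -0.00283 /s   mio = -9.74e-05
AUCi = 48.4   AUCf = 8.0   residual = 1.3%
```

i.e. the fit recovers the planted onset (30 s) and time-to-peak
(τ = ln(0.10/0.006)/0.094 ≈ 29.9 s) from a noisy sampled curve; `wi` is
the uptake rate in normalised enhancement per second, negative `wo` is the
post-peak decline, and the residual is the mean absolute misfit as a
percentage of the curve's dynamic range.

A full synthetic study runs from the shell:

```bash
dcehab run-all --out results/run1 --seed 1 --n-patients 40
```

which writes per-biopsy features, the ranked DCE single/pair table, the
ADC-pair and quadruple rankings, DeLong comparisons with the FDR-adjusted
threshold, and a manifest with conserved patient/biopsy counts.
`dcehab simulate`, `preprocess`, `habitat`, `fit-curves`, `adc-features`
and `evaluate` expose the individual stages.

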