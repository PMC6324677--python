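# Methods

## Curve model and fitting

Enhancement is modelled as `s(t) = s0 + A(e^{−k_out u} − e^{−k_in u})` for
`u = t − t0 > 0` and `s(t) = s0` before onset. This difference-of-
exponentials form is the canonical semi-quantitative "bi-exponential" DCE
model: it produces a flat baseline, a wash-in limb, a peak and a wash-out
limb from five parameters, and gives the time-to-peak
`τ = ln(k_in/k_out)/(k_in−k_out)` and both AUC windows in closed form. It
deliberately avoids pharmacokinetic modelling (no arterial input function
deconvolution, no Ktrans/Kep); its parameters describe curve shape, not
contrast exchange physiology.

Fitting is trust-region nonlinear least squares (`scipy.optimize.
least_squares`, analytic Jacobian) over `(s0, A, t0, k_out, Δk)` with
`k_in = k_out + Δk` and bounds `A ≥ 0`, `Δk ≥ 1e−5`, so the `k_in > k_out`
branch is structurally enforced. Starts come from a fixed deterministic
grid over t0 (fractions of the interval from the first frame to the
empirical peak), `k_in ∈ {0.02…0.4}` and `k_out ∈ {1e−4…0.02}` s⁻¹, with
the baseline and amplitude solved linearly at each node; the three best
nodes are refined (single-curve API) and the best refinement wins. No
randomness enters the fit, so results are reproducible bit-for-bit. An
(almost) constant curve short-circuits to a flagged `A = 0` fit whose
descriptors are all zero. The batch fitter used for voxel-wise maps
vectorises the grid stage across voxels and refines only the best node per
voxel — the measured accuracy cost on synthetic curves is negligible and
it is what makes per-voxel mapping tractable on one CPU.

The wash-out slope `wo` is defined as the mean slope of the *fitted* curve
from its peak to 270 s after onset, `(s(t0+270) − s_m)/(270 − τ)`: a
single number with slope units, consistent with the slope product
`mio = wi·wo`. (An instantaneous post-peak slope would depend strongly on
where it is evaluated; the mean slope over the late window does not.) Both
AUC features integrate the fitted, baseline-subtracted curve in closed
form, so a flat curve scores exactly zero. When the acquisition is shorter
than `t0 + 270` s the analytic model extrapolates the late window and the
feature vector is flagged; when `τ ≥ 270` s there is no peak inside the
window and `wo`, `mio` are zeroed with a flag.

## Pre-processing

- Series with temporal resolution ≥ 15 s per frame are excluded (curve
  descriptors are unreliable at that sampling); motion exclusion is an
  input flag, since it comes from visual review, not from the data.
- ADC maps are z-scored within the prostate using the population
  (divide-by-N) standard deviation — the mask is the entire population of
  gland voxels, not a sample.
- DCE normalisation shifts each voxel curve by its own mean pre-contrast
  value and divides the whole series by one scalar, the arterial peak
  enhancement (max of the mean artery curve minus its pre-contrast mean).
  A single scalar preserves curve *shape*, which is all downstream
  features use; it also makes the pipeline invariant to global intensity
  rescaling, which is tested.
- Registration quality is reported as 100 · mean_t |raw − fit| / (s_m −
  s0) of the mean prostate curve: residual temporal misalignment breaks
  the smooth bi-exponential shape and inflates the metric. The
  denominator (fitted dynamic range) makes the percentage scale-invariant
  and defined for every non-degenerate curve.

## Habitat localisation

The voxel-wise `wi` map is defined inside the prostate; degenerate voxel
fits contribute `wi = 0` rather than being dropped, so percentile pools
keep their geometric size. The search region is a sphere of radius 15 mm
around the biopsy point — voxel-centre membership in mm, honouring
anisotropic spacing — clipped to the prostate and to the zone (PZ or TZ)
containing the larger share of the lesion contour; with no contour the
zone of the biopsy point decides. The habitat keeps voxels at or above
the 75th percentile (linear-interpolation quantile) of `wi` within the
search region; ties at the threshold are *included*, which keeps the rule
deterministic and the region at least a quarter of the search volume. An
all-equal map returns the whole region, flagged. The habitat's mean curve
at each frame is the representative curve refitted for the seven
descriptors.

The orchestration computes the `wi` map only over each biopsy's bounded
search sphere — the exact voxel set the quartile rule reads — rather than
the whole gland; the map API accepts any mask including the full prostate,
and the two agree on the shared voxels by construction.

## ADC radiomics

Histogram features use 16 equal-width bins over the region's own
[min, max]; habitat regions hold ~10²–10³ voxels, for which a small fixed
bin count is stable. The histogram gradient is a central difference on
bin counts (one-sided at the edges); ties resolve to the lowest grey
level. The intensity-volume-histogram features use the 10%/90%
conventions: `VolIFractDiff = V10 − V90` (volume fractions above 10%/90%
of the intensity range) and `IntVFractDiff = I10 − I90` (intensities at
10%/90% volume fractions). Surface area counts exposed voxel faces in
mm² — exactly testable, mesh-free, with a documented overestimation bias
relative to marching-cubes surfaces. Axis lengths are `4√λ_i` of the
voxel-centre coordinate covariance eigenvalues (the matching-moments
ellipsoid); a digitised ball of radius R gives `4R/√5` within
discretisation error. Texture matrices (GLCM etc.) are out of scope.

## Classification and statistics

The classifier is a CART decision tree capped at depth 3 with a fixed
seed: at cohort sizes of 40–100 biopsies deeper trees make leave-one-out
unstable. Sensitivity and specificity come from hard class predictions,
AUC from class-probability scores. SMOTE is implemented directly
(k = 5 minority nearest neighbours, uniform interpolation weight,
seeded), over-sampling the minority class to exact parity; majority
samples are never altered. In leave-one-out, SMOTE runs inside each
training fold only, so the held-out biopsy can never leak into the
balanced set (verified by test); a global-balancing mode exists for
comparison and flags its results as leaky. The evaluation unit is the
biopsy;
patient IDs are carried for grouped analyses. Cross-cohort validation
balances the whole training cohort once and scores the other cohort
unbalanced.

The exhaustive search evaluates the 7 single descriptors and 21 unordered
pairs (28 runs), and optionally each DCE pair crossed with the top-ranked
ADC pairs (21 × 5 = 105 quadruples). DeLong's paired test compares each
tuple's pooled LOO scores against the top tuple via the structural
components of the Mann–Whitney statistic; the 27 resulting p-values form
the multiple-comparison family corrected by Benjamini–Hochberg step-up,
reporting the adjusted threshold `p_(k)`.

## Synthetic cohort

The generator plants what the analysis assumes: an ellipsoidal prostate
(default semi-axes 22 × 18 × 16 mm) split into an inner-ellipsoid
transition zone (62% linear fraction) and a peripheral-zone shell;
spherical lesions (4–7 mm radius) wholly inside the gland; a weakly
enhancing gland background; an arterial tube with an early (t0 = 16 s)
high-amplitude bolus; additive Gaussian noise on magnitude intensities (a
high-SNR approximation to Rician noise that keeps curve-fit oracles
exact); an ADC map with bright background, intermediate gland and darker
lesions. Significant lesions draw `k_in ~ N(0.10, 0.01)` s⁻¹, amplitude
N(90, 10) and ADC N(700, 60); insignificant lesions `k_in ~ N(0.04,
0.01)`, amplitude N(60, 10), ADC N(1150, 90) — wash-in-rate and ADC
separations of roughly 5–6 pooled standard deviations, a deliberately
learnable effect. Biopsy points are lesion centres of mass jittered
uniformly in a 3 mm ball (fusion error); the simulated radiologist
contour is the lesion dilated by 2 mm. Everything is deterministic given
(master seed, patient index).

What the generator does **not** emulate: realistic anatomy, partial-volume
effects, B-field inhomogeneity, motion, k-space artifacts, within-lesion
parameter heterogeneity, or the unknown per-class perfusion distributions
of real cohorts. Passing tests therefore demonstrate that the chain
recovers planted effects of stated size under idealised geometry and
noise — not that real cohorts would yield any particular AUC, and the
published per-institution performance of habitat descriptors is not a
quantity this synthetic study can reproduce.

## Problem sizes and numerical choices

The end-to-end study uses 40 patients on a 64³ grid at 2 mm spacing with
40 frames at 7 s — sizes chosen so the full pipeline (per-voxel fitting
inside the bounded spheres, 28 + 105 tuple evaluations, DeLong + FDR)
completes in a few minutes on one CPU while leaving dozens of biopsies
per class analysis. Quantile: NumPy's linear-interpolation estimator.
Exponential arguments are clipped at −700 to avoid underflow warnings.
Fit tolerances are 1e−14 (single curve) and 1e−10 (batch). Degenerate
inputs (constant curves, flat arteries, constant ADC, empty regions,
single-voxel masks) either raise descriptive errors or return flagged
zero features, as documented per function.

## Known limitations

- Time-to-peak is only as well conditioned as the temporal sampling: for
  sharp curves whose τ is shorter than about two frame intervals, noise
  moves the apparent peak by a large *relative* amount, and the 10%
  median-error figure quoted for the representative lesion curve does not
  transfer to such curves.
- The sum-of-two-exponentials form cannot represent persistently rising
  ("type 1") curves with a finite peak; they fit with very small `k_out`
  and τ beyond the wash-out window, and are flagged.
- Voxel-face surface area overestimates smooth-surface area by up to
  ~50% for spheres at coarse spacing; it is used consistently, so
  comparisons across regions remain meaningful.
- The arterial normalisation is a per-series scalar; it does not attempt
  to recover contrast-agent concentration.
- Shallow trees give coarse probability scores, so LOO AUCs are computed
  from few distinct score levels; ties are handled by the Mann–Whitney
  convention.
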