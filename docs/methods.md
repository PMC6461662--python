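# Methods

## Scope and data model

The unit of analysis is one segmented subsolid nodule: a CT-attenuation
histogram (voxel counts over uniformly spaced HU bins inside the window
[−1000, 500] HU; default 151 bins of 10 HU centred at −1000 … 500) plus
geometric measurements (volume in mm³; min/mean/max diameter and maximum
consolidation diameter in mm) and a binary pathology label
(T1 = AAH/AIS/MIA vs T2 = IPA). Because the original patient cohort is not
public, a synthetic generator provides seeded surrogate cohorts; everything
downstream of the generator is the analysis pipeline proper and works
unchanged on real exported histograms.

## Synthetic cohort generator

### Marginals (closed-form calibration)

Each per-class marginal is chosen as a standard positive/skewed family and
solved exactly from the published per-class (median, IQR):

| quantity | family | calibration |
|---|---|---|
| volume | log-normal | `σ = asinh(IQR/2·median)/z₇₅`, `μ = log median` |
| mean diameter | log-normal | same closed form |
| max/min diameter ratio − 1 | log-normal | same closed form |
| consolidation ratio | logit-normal | `μ = logit(median)`, σ by 1-D root find |
| per-nodule mean HU | normal | `σ = IQR/(2 z₇₅)` |
| ground-glass SD (nuisance) | log-normal | median 150 (T1) / 190 (T2) HU, log-SD 0.2 |

with `z₇₅ = Φ⁻¹(0.75) ≈ 0.6745`. Defaults encode the published class
statistics (T1/T2): volume 1129/3459 mm³ (IQR 2218/5754), mean diameter
14/20 mm, ratio 1.37/1.67, consolidation ratio 0.29/0.76, mean HU −639/−442
(IQR 169/225.5). Min/max diameters are `D/√ρ` and `D·√ρ` (geometric split of
the irregularity ratio ρ around the mean diameter D), and the maximum
consolidation is `cr · max diameter`, so the recomputed consolidation ratio
reproduces its logit-normal marginal exactly. The log-normal volume choice
makes the conventional log₁₀-volume operating threshold (~3.1 for ~1.3 cm³)
fall between the class medians, as it should.

These marginals *imply* the univariate discriminations observed in the
study — binormal closed forms give AUC ≈ 0.83 for mean HU, 0.74 for
log-volume, 0.73 for diameter ratio — which is the package's main evidence
that the published per-class distributions and the published univariate
AUCs are mutually consistent. Those AUCs are emergent, not fitted.

### Correlation

A Gaussian copula on the six base variables induces rank correlation
without touching the calibrated marginals. The default latent correlation
(see `default_latent_correlation`) encodes: volume–diameter 0.85;
mean HU–consolidation 0.6; mean HU–ground-glass SD 0.45; everything
involving the irregularity ratio ≈ 0.1. This mirrors the qualitative
correlogram structure of such cohorts (attenuation features strongly
inter-correlated, size features inter-correlated, irregularity nearly
independent); it is validated only qualitatively.

### Histograms

Each nodule's histogram is a multinomial draw (total voxels =
volume / voxel volume, default voxel 0.7×0.7×2.5 mm³, floor 50, cap 5·10⁵)
from a two-component Gaussian mixture truncated to the attenuation window:

* a **ground-glass** component `N(g, s_g²)` and
* a **solid** component `N(50, 120²)` HU with mixture weight
  `w = 0.4 · cr³` (a volume-fraction proxy of the consolidation ratio, so
  T1 nodules are essentially unimodal and T2 nodules bimodal);

the ground-glass location `g` is solved per nodule (vectorised bisection on
the truncated-normal mean) so that the truncated-mixture mean equals the
drawn mean-HU target. Realised class medians of the histogram mean are
therefore on target by construction; the per-nodule IQR/SD/skewness
features emerge from `s_g`, `w` and the component separation (class medians
land within a few percent of the published 197/348 HU IQRs). Mean-HU
targets are clipped to the reachable band of the truncated mixture
(≈[−890, 440] HU); this affects only the extreme tails, not medians.

### Reader perturbation

The second reader's cohort applies multiplicative log-normal jitter to
volume (log-SD 0.10), each diameter (0.05, re-sorted to preserve
min ≤ mean ≤ max) and consolidation (0.10, clipped at the max diameter),
and relocates each histogram bin's voxels by an additive `N(0, 20 HU)`
offset before re-binning (mass-conserving). The magnitudes were calibrated
once so that refitting model 1 on the perturbed cohort reproduces the
reported predicted-class agreement (kappa ≈ 0.95); a scan over
0.25×/1×/3× noise confirms kappa degrades monotonically with magnitude.

## Feature conventions

* Moments are population (no small-sample correction) count-weighted
  moments over bin centers; kurtosis is Pearson (Gaussian = 3).
* Quantiles invert the piecewise-linear CDF that spreads each bin's mass
  uniformly across the bin.
* Degenerate histograms (all mass in one bin) raise an error naming the
  nodule rather than returning undefined shape statistics.

## Density FPCA

Histograms are smoothed by a Gaussian kernel on the bin centers with
boundary reflection at both window edges (mass-preserving); the default
bandwidth is Silverman's rule on the count-weighted sample, floored at half
a bin width. The density is floored at δ = 10⁻⁵ per HU and renormalised so
the LQD transform `ψ(p) = −log f(Q(p))` is finite; `Q` comes from monotone
interpolation of the trapezoid CDF on a 101-point probability grid.

FPCA is the eigendecomposition of the 1/n sample covariance operator under
the trapezoid inner product (computed via the symmetric
`W^{1/2} C W^{1/2}` form, so eigenfunctions are exactly orthonormal in the
weighted geometry); components are retained up to 85% cumulative explained
variance, minimum two. Eigenfunction signs are fixed by a positive
trapezoid integral (positive inner product with the constant upward-shift
direction; mid-grid positivity as tie-break). Under this convention, on
default synthetic cohorts, higher FPC1 corresponds to wider, higher-
attenuation (more heterogeneous) densities — verified by the
mode-of-variation curves — and FPC1 correlates far more strongly with the
invasiveness label than FPC2. The sign orientation is a package
convention; the originating analysis is internally ambiguous about its own
orientation, so no attempt is made to match a particular published sign.

The inverse LQD map integrates `q = e^ψ` on a monotone-cubic (PCHIP)
refinement of the probability grid and rescales so the reconstructed
support width is exactly 1500 HU; adding a constant to ψ therefore leaves
the reconstructed density invariant. **Conditioning caveat**: for densities
whose tails sit at the δ-floor, the quantile density spikes to 1/δ over
sub-grid probability widths, and a 101-point LQD sample cannot represent
the corner; round-trip reconstruction is then only approximate. The
round-trip contract (L1 < 10⁻³) holds for smooth truncated Gaussians with
scale comparable to the window; FPCA itself operates entirely in the LQD
domain and is unaffected.

## Modeling

* Univariate AUC is the Mann-Whitney rank statistic (ties ½), reported in
  the direction making AUC ≥ 0.5; the operating threshold maximises
  Youden's J over midpoints of adjacent distinct values (smallest wins
  ties); CIs are stratified-bootstrap percentiles (2000 resamples).
* Correlation screening: Pearson r with two-sided Fisher-Z p-values;
  |r| ≥ 0.9 pairs are flagged with the lower-AUC member marked for
  discard; zero-variance columns are reported, never fatal.
* Logistic fits are unpenalised maximum likelihood (lbfgs) on internally
  standardised predictors; perfect separation is detected (error-free
  in-sample prediction with standardised |coef| > 8) and surfaced as a
  warning with finite coefficients.
* Repeated stratified 10-fold CV (default 100 repeats) learns all
  preprocessing inside training folds, pools out-of-fold probabilities per
  repeat, and summarises per-repeat AUC/accuracy/sensitivity/specificity
  (0.5 probability threshold) by the mean and the 2.5/97.5 percentile
  interval across repeats. The percentile-across-repeats interval is a
  documented package choice; it reflects fold-assignment variability only.
* FPC scores are computed once on the full cohort before CV (matching the
  original analysis); `ModelingConfig.fpca_within_folds` exists as a flag
  for the leakage-free alternative but is off by default.
* Calibration follows the bootstrap optimism-correction scheme for
  logistic models: lowess (frac 2/3) of outcome on predicted probability,
  apparent-minus-test optimism averaged over 200 bootstrap refits, error =
  mean |corrected − predicted|. On well-specified synthetic cohorts this
  error is small (~0.02); the original report's ~0.1 reflects real-data
  misfit that the generator does not emulate.

## Agreement

Cohen's kappa (binary, with paired-subject percentile bootstrap) and
ICC(2,1) — two-way random effects, absolute agreement, single measure,
from the mean-squares decomposition — quantify predicted-class and
predicted-probability agreement between the two reader cohorts. Agreement
is computed on the full cohort (the original split between training and
testing material for this statistic is not recoverable). Both statistics
are cross-checked in the test suite against independent implementations
(scikit-learn's kappa, pingouin's ICC).

## Determinism and problem sizes

A master seed spawns named streams (cohort, reader, CV, bootstrap), so
changing one stage's resampling count does not perturb the others; two
runs with identical seed and config are byte-identical on disk (run logs
carry no wall-clock timestamps). Cohort-level calibration checks use 200
replicate cohorts of the study's 56+53 size; smoke and determinism tests
use reduced sizes (14+14 nodules, 3 folds × 3 repeats) as the package's
standard quick-check scale.

## What passing tests do and do not show

The generator reproduces the published *marginal* per-class summaries, the
univariate discriminations they imply, and the reported agreement level.
It does not emulate scanner/protocol heterogeneity, segmentation error
beyond the parametric jitter model, spatial texture (there is no voxel
phantom), multi-nodule patients, or real-data model misfit; cross-validated
multivariate AUCs on synthetic cohorts (~0.90) should therefore be read as
consistency checks of the pipeline, not as independent evidence about
patient data.

## Known limitations

* The LQD round-trip is ill-conditioned at the density floor (above).
* Histogram export conventions (bin width, counts vs frequencies) of the
  original workstation are unknown; the CSV dialect here is a stand-in.
* Small synthetic cohorts occasionally separate perfectly inside CV folds;
  the separation warning is expected there and coefficients remain finite.
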