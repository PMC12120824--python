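# Methods

## Data model

The unit of analysis is a region-level observation: one QCS spot or one
tissue section, summarized upstream (outside this package) to a single
non-negative abundance per m/z feature. A `FeatureTable` holds the
n_obs × n_feat intensity matrix together with observation metadata
(slide, day, global 1-based measurement order, region type, tissue
group, optional within-slide row label) and feature metadata (feat_id,
m/z, role: analyte / internal_standard / tissue_feature). Intensities
are stored on the raw linear scale; methods that need a log scale apply
it internally and never persist it. Missing values are rejected at
read time with the offending row/column named — region-level MSI
exports are complete by construction, so an absent value indicates a
corrupted table, not censoring. Whether upstream abundances are
per-region means or sums is deliberately left open: every statistic
here is invariant to that choice except by a global factor, and the
reader accepts any non-negative value.

`measurement_order` is global across the experiment (not per slide)
because drift correction operates on the full acquisition sequence.

## Variation metrics (Part 1)

* **CV%** is 100·sd/mean with the sample standard deviation (n−1).
  Intraday CV pools all QCS analyte values of one day across that day's
  slides; interday CV pools the whole experiment. Pooling (rather than
  averaging daily CVs) is the convention that a single experiment-wide
  CV definition supports. Grouping cells with fewer than two
  observations are reported as explicit NA, never dropped.
* **Kruskal–Wallis** (tie-corrected H, chi-square approximation with
  k−1 df, via `scipy.stats.kruskal`) tests day and slide differences in
  QCS intensity. The total-tie degenerate case (all values identical)
  is defined as (H, p) = (0, 1): no evidence of batch difference.
* **Outlier slides.** Per-slide medians of the QCS analyte are taken on
  the log scale — the error model is multiplicative, so a symmetric
  rule on the raw scale would under-weight attenuated slides — and
  centered on their day cohort's median before a global scaled-MAD
  z-score (cutoff k = 3.5, MAD × 1.4826). Day-centering matters: a
  slide failure (e.g. a matrix-sprayer event) is an anomaly relative to
  its own day, and leaving ordinary day-level shifts in the spread
  inflates the MAD enough to mask genuine single-slide attenuations of
  the magnitude the generator injects. With a zero MAD the rule falls
  back to flagging any slide whose centered median differs exactly.
  An outlier finding is advisory, not blocking (`--strict` makes it
  blocking): corrections are expected to handle flagged slides.
* **Drift** is summarized descriptively (no p-value): mean analyte
  intensity versus measurement order, least-squares slopes on the raw
  and log scales, and a per-slide paired contrast of QCS acquired after
  versus before the slide's tissue regions (NA when a slide lacks one
  side).

## Normalization

TIC normalization divides each observation's features by their sum over
all feature columns of the supplied table; it is region-scoped in the
sense that whatever table is passed in defines the sum. It is
idempotent and scale-invariant per observation. IS normalization
replaces the analyte column by the analyte/IS ratio and touches nothing
else — an isotope-labelled standard exists only for the spiked analyte,
not for endogenous panels. Any multiplicative factor shared by the two
columns cancels exactly, which is the mechanism by which the IS ratio
reaches the residual-noise floor. Z-scoring (for violin-plot style
display) pools all observations of a feature so slide-level shifts stay
visible; it is display-only and never feeds CV computation, which a
z-score would destroy.

## ComBat (empirical-Bayes location/scale)

Runs on log(x + ε), ε = half the smallest positive value in the table;
the batch structure of MSI abundances is multiplicative (the ratio
normalizations only cancel multiplicative artifacts), so a log-additive
location/scale model is the natural working scale. Steps: (1) per
feature, batch means and the weighted grand mean α_g (weights n_i/N),
giving γ̂_ig with Σᵢ n_i γ̂_ig = 0; pooled variance σ̂²_g from
residuals (denominator N); (2) standardize Z = (Y − α_g)/σ̂_g; (3)
per-batch feature-wise moments give the Normal prior (γ̄_i, τ̄²_i) for
locations and method-of-moments inverse-gamma hyperparameters
(λ̄_i, θ̄_i) for the per-batch variances of Z; (4) iterate the
conditional posterior means

    γ*_ig = (n_i τ̄²_i γ̂_ig + δ*²_ig γ̄_i)/(n_i τ̄²_i + δ*²_ig)
    δ*²_ig = (θ̄_i + ½ Σ_j (Z_ijg − γ*_ig)²)/(n_i/2 + λ̄_i − 1)

to a max-absolute change below 1e-4 (cap 100 iterations); (5) adjust
Y* = σ̂_g/δ*_ig·(Z − γ*_ig) + α_g and back-transform, clipping at zero.
Corrections run unsupervised — no biological covariates — on QCS and
tissue observations together, with `day` as the default batch key
(`slide_id` available via config). Zero-variance features are left
untouched with a log entry; a single-batch input is returned unchanged;
batches of one observation are an error. When the feature panel is too
small for method-of-moments priors (fewer than two usable features),
shrinkage is skipped for that batch. Only the parametric EB variant is
implemented. The implementation agrees with Bioconductor `sva::ComBat`
to ~1e-4 on shared fixtures (the residual difference is the two
solvers' different stopping criteria).

## WaveICA (wavelet + ICA)

Observations are sorted by measurement order and, like ComBat,
processed as log(x + ε). Each feature's series is decomposed with a
maximal-overlap discrete wavelet transform (MODWT) — the
shift-invariant, non-decimated DWT variant defined for any series
length — to J = ⌊log₂ n⌋ detail levels plus the final smooth, using a
reflection boundary (the series extended by its mirror image) so the
circular transform never wraps the last batch onto the first; the
wavelet filters come from PyWavelets, rescaled by 1/√2. Per level
(details and smooth), FastICA (deflation, negentropy/logcosh, fixed
seed) extracts K = min(20, n−1, n_feat) components, further capped at
the number of directions carrying 99% of that level's variance —
whitening numerically tiny directions up to unit variance would dilute
a dominant batch pattern across components and hide it from the
association test. Each component's score vector is scored by R²
against batch-indicator dummies (sign- and scale-invariant, so ICA's
sign/order indeterminacy is irrelevant); components at or above the
threshold (default 0.05) are subtracted from the level matrix, the
transform is inverted on the extended series, and the two mirror halves
are averaged. With a threshold above 1 nothing is removed and the
output equals the input to floating-point roundoff. The MODWT
conserves energy exactly, which the tests exploit as an invariant.

## Multivariate evaluation (Part 2)

PCA is fit with centering and unit-variance scaling (zero-variance
features dropped with a record), SVD-based, with a deterministic sign
convention (largest-magnitude loading positive). Proximity metrics use
exactly PC1–PC2: intragroup distance is the mean Euclidean distance of
group members to their centroid; intergroup distance is the average of
pairwise centroid distances. The QCS proximity ("distance in PCA") is
the intragroup distance of all QCS spots treated as one group, in a PCA
fit on the combined QCS + tissue table — QCS and tissue appear in one
score space, and the metric reflects QCS scatter in terms of all
detected features. For IS-normalized tables the full-feature metrics
are reported NA as a policy: only the analyte column was transformed,
so a full-feature PCA of that table is not a property of the method.

PLS-DA uses a one-hot (centered) response with NIPALS PLS2
(`sklearn.cross_decomposition.PLSRegression` on autoscaled features)
and A = (number of groups − 1) components by default. VIP scores are

    VIP_j = sqrt( p · Σ_a SS_a (w_aj/‖w_a‖)² / Σ_a SS_a ),
    SS_a = (tₐ'tₐ)(qₐ'qₐ)

which satisfies mean(VIP²) = 1 identically; features with VIP > 1.2
(the conventional distinctiveness cutoff, configurable) are selected.
The cross-method comparison marks a feature *robust* when selected
under every method and *dropped* when selected in the raw table but
under no corrected method.

## Synthetic generator

Log-scale model, natural log:

    log x_of = μ_{g(o),f} + b_{s(o)} + c_{d(o)} + β_f·order(o)
               + u_{s(o)}·1[outlier] + ε_of,   ε ~ N(0, σ²)

Defaults emulate the study design: 3 days × 6 slides, groups balanced
within day (2 slides per group per day), 6 QCS spots per slide — three
acquired before and three after the slide's 4 tissue-region
observations, so the drift contrast is exercised — 200 tissue features
(30% "lipid-like", m/z > 700, carrying drift slopes drawn uniformly
from [−0.006, −0.002] per order unit), σ_slide = 0.3, σ_day = 0.2,
σ_resid = 0.1, one outlier slide (S4, day 1) attenuated by −1.5 log
units, 10 marker features per group with a 1.0 log effect. Slide order
is randomized within day; measurement order is global and day-blocked.
The analyte (linear baseline 1000) and IS (500, i.e. a 2:1 spike
ratio) share b, c and u and do not drift; the IS has its own residual,
so the analyte/IS ratio is log-normal with sd √2·σ_resid — CV ≈ 14.2%
at the defaults, at the validation ceiling's edge by construction of
the residual noise level, not by tuning. Tissue features appear in QCS
spots at a 0.05 baseline factor (biological features present at trace
level in the gelatin standard). Four tissue-region observations per
slide is a package choice (enough observations for PLS-DA and the
paired drift contrast while keeping one section per slide plausible).

σ_slide and σ_day are calibrations, not estimates: real slide- and
day-level variance cannot be separated from published summary tables,
so the defaults are chosen to reproduce the observed CV regime (raw
interday CV in the tens of percent, IS ratio near 14%) and documented
as such. Realized per-seed CVs are dispersed (roughly 27–62% for raw
at these defaults), so regime statements are made about means over a
20-seed replicate panel, not single runs.

`SyntheticTruth` records the realized b, c, β, u and marker sets.
Recovery helpers condition on the truth terms they are not estimating:
`recover_slide_effect_slope` subtracts the known day and outlier terms
and averages the analyte and IS log-means (both carry b_s) before
regressing on b_s — the clustered day variance and the −1.5 outlier
term would otherwise sit in the residual and make an unbiased slope
estimate noisy at 18 slides regardless of generator quality.
`recover_drift_slopes` likewise residualizes the known slide/day/outlier
terms before the per-feature OLS on order.

What the generator does *not* emulate: pixel-level spatial structure,
peak-shape or m/z-axis artifacts, missingness, correlated residuals
between tissue features, and the compositional richness of real
spectra. One visible consequence: after TIC normalization the
simulated QCS spectra are dominated by two features (analyte + IS), so
autoscaled PCA amplifies their compositional noise and the QCS
proximity metric *increases* under TIC here, whereas on real data (with
hundreds of QCS-visible features) TIC tightened the QCS cluster.
Passing tests therefore validate the machinery and the directional
claims on abundance-scale methods, not that metric's behaviour under
ratio normalization on real spectra.

## Numerical and design choices

* Log offset ε = 0.5 × smallest positive intensity: keeps zeros finite
  while perturbing genuine values negligibly.
* ICA seed is fixed and recorded in the `CorrectionResult`; components
  are scored only through R², which is invariant to ICA's sign and
  order indeterminacy.
* Corrections never run supervised; the method grid (raw, TIC, IS,
  TIC+ComBat, TIC+WaveICA, ComBat, WaveICA) is labelled with the
  conventional printed row names. External correctors (e.g. a
  deep-learning method trained elsewhere) can be attached through
  `register_correction`; they are out of native scope.
* Determinism: (input CSV, config, seed) fully determine all outputs;
  report CSV bodies are written with a fixed float format and verified
  byte-identical across re-runs.
* The CSV writer emits `repr(float)` so values round-trip exactly.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the generator at the
default design (180 observations × 202 features), with 10-seed panels
for the correction-grid comparisons and 20-seed panels for recovery
and outlier-detection rates; the closed-form CV check also uses a
5× larger QCS panel to show the estimate tightening with n. These
sizes give stable panel means while keeping a full run in the order of
seconds to a minute on one CPU.

## Known limitations

* ComBat assumes a log-additive location/scale batch model; nonlinear
  batch structure is out of scope (pluggable registry exists for
  external nonlinear correctors).
* WaveICA's component removal subtracts batch-associated variance from
  *all* features at once; on data where batch structure is weak it can
  slightly reshuffle per-feature variance (visible as occasional
  per-seed CV increases even as day-level spread shrinks).
* The nonparametric ComBat variant and permutation-based PLS-DA
  validation are not implemented.
* No imzML/vendor readers and no pixel-level spatial metrics:
  observations enter as region-level abundances from upstream spectral
  preprocessing.
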