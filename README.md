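# msibatch

Batch-effect evaluation and correction for mass-spectrometry-imaging
(MSI) feature tables, driven by quality-control standards (QCS).

In multi-day MALDI-MSI studies, technical variation — matrix spraying,
matrix degradation, ionization efficiency, ion-source drift, detector
performance — accumulates at the slide and day level and can mask or
mimic biology. A tissue-mimicking QCS (e.g. propranolol in gelatin,
optionally with an isotope-labelled internal standard, propranolol-d7)
co-measured on every slide makes that variation observable. `msibatch`
turns the resulting wide feature tables (observations = QCS spots or
tissue sections, columns = m/z features) into a two-part workflow:

* **Part 1 — evaluation.** Intraday/interday coefficients of variation
  of the QCS analyte (CV% = 100·sd/mean, sample sd), Kruskal–Wallis
  rank tests of batch differences, robust (MAD-based) outlier-slide
  flagging, and acquisition-order drift profiles.
* **Part 2 — correction + re-evaluation.** A method grid — no
  normalization, TIC (total-ion-current) normalization x̃ᵢⱼ = xᵢⱼ/Σⱼxᵢⱼ,
  internal-standard ratioing, and native implementations of two batch
  correctors — each cell re-evaluated with the QCS metrics plus
  multivariate tissue metrics (PCA intragroup/intergroup distances in
  the PC1–PC2 plane, median tissue-feature CV%, PLS-DA VIP feature
  selection at the conventional VIP > 1.2 cutoff).

The two native correctors are:

* **ComBat** — empirical-Bayes location/scale adjustment. Per feature
  *g* and batch *i*, log intensities are modelled as
  α_g + γ_ig + δ_ig·ε; batch locations γ̂ and scales δ̂² are shrunk
  toward Normal / inverse-gamma priors (method-of-moments
  hyperparameters) by iterating the conditional posterior means, then
  the data are standardized, adjusted and restored. Verified against
  `sva::ComBat` to ~1e-4 (the two solvers differ only in their EB
  stopping rule).
* **WaveICA** — drift/batch removal along measurement order. Each
  feature's ordered intensity series is decomposed with a
  maximal-overlap discrete wavelet transform (shift-invariant, any
  series length, reflection boundary), independent components are
  extracted per wavelet level (FastICA, deflation), components whose
  score vectors are batch-associated (R² against batch indicators ≥ a
  threshold, default 0.05) are subtracted, and the transform is
  inverted. With nothing removed the round trip is exact.

Because no public instrument data exist for this design, the package
ships a first-class synthetic generator (`msibatch.simulate`) that
emulates the study: 3 tissue groups × 6 replicate slides over 3 days,
6 QCS spots per slide bracketing the tissue regions, ~200 tissue
features plus analyte/IS, with log-normal slide/day effects, an
attenuated outlier slide, and negative acquisition drift on
"lipid-like" (m/z > 700) features — all with exact ground truth for
parameter-recovery testing.

## Worked example

```python
from msibatch import PipelineConfig, generate_batch_experiment, run_part1, run_part2

table, truth = generate_batch_experiment(seed=0)   # 180 obs x 202 features
report, clean = run_part1(table)
print("interday CV%%: %.2f" % report.interday_cv)
print("flagged outlier slides:",
      list(report.outlier_slides.loc[report.outlier_slides.flagged, "slide_id"]))

cmp = run_part2(table, PipelineConfig(seed=0), skip_part1=True)
print(cmp.grid[["interday_cv", "pca_distance", "tissue_median_cv"]].round(2))
```

prints

```
interday CV%: 38.10
flagged outlier slides: ['S4']
               interday_cv  pca_distance  tissue_median_cv
raw                  38.10          0.34             39.24
TIC                   9.94          5.29             12.01
IS                   13.43           NaN               NaN
TIC + Combat          9.91          2.14             10.52
TIC + WaveICA         9.17          1.57             10.15
Combat               31.58          0.29             31.02
WaveICA              31.78          0.27             31.99
```

Reading this: the raw QCS analyte varies by 38% across the experiment
and the generator's deliberately attenuated slide S4 is caught by the
robust rule. Every correction lowers the interday CV; the IS ratio
lands near its theoretical floor (the residual-noise CV, ~14%) and
below the conventional 15% bioanalytical ceiling; the `IS` row's
full-feature metrics are not applicable because IS ratioing transforms
only the analyte column. `tissue_median_cv` is the median CV% of the
tissue features across tissue sections — the corrections that cancel
the shared multiplicative structure (TIC-based cells) cut it from ~39%
to ~10%.

The same workflow is available from the shell:

```sh
msibatch simulate --seed 0 -o table.csv --truth truth.json
msibatch evaluate -i table.csv -o part1/
msibatch run -i table.csv --seed 0 -o report/
```

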