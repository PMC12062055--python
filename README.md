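# epidmd

Dynamic mode decomposition (DMD) for county-level disease-incidence panels,
benchmarked against standard forecasting baselines.

## The problem

Public-health surveillance produces spatiotemporal panels: an age-adjusted
incidence rate (cases per 100,000) for each of ~1,000 US counties, keyed by
5-digit FIPS code, observed annually over ~two decades. Practitioners want
two things from such a panel: a one-year-ahead forecast for every county,
and an interpretable account of the spatial and temporal structure driving
the trend — which regions are persistently high, and how fast the overall
level is decaying.

`epidmd` addresses both with exact DMD. Stacking the annual snapshots
x_1..x_m (one rate per county) into shifted matrices X1 = [x_1..x_{m-1}]
and X2 = [x_2..x_m], the best-fit linear propagator is A = X2 X1⁺. It is
never formed at county dimension; instead a rank-r SVD X1 ≈ UΣV* gives the
reduced operator

    Ã = U* X2 V Σ⁻¹,

whose eigenpairs (λ, w) yield the DMD eigenvalues and, through
Φ = X2 V Σ⁻¹ W, the spatial modes. Each mode is one complex loading per
county evolving geometrically: |λ| < 1 decays, arg λ is the oscillation
frequency per year. With amplitudes b fitted to the first snapshot
(Φb ≈ x_1), the forecast is

    x_k ≈ Re( Φ Λ^{k-1} b ).

The dominant zero-frequency mode maps the steady geography of the rates (a
choropleth-ready `fips, magnitude` table); the eigenvalue spectrum relative
to the unit circle, the rank sweep (holdout RMSE and retained singular-value
energy per truncation rank), and a six-model comparison — DMD, Holt
exponential smoothing with trend, lagged linear regression, random forest,
gradient boosting, and RBF-kernel SVR, scored by RMSE and Spearman rank
correlation — round out the analysis.

Registry extracts are distributed under data-use agreements, so the package
ships a synthetic generator (`epidmd.synthetic`) that simulates panels from
a known low-rank linear system with spatially clustered high/low blocks and
observation noise, retaining the generating eigenvalues, modes and
amplitudes for exact parameter-recovery tests.

## Worked example

Generate a 200-county, 22-year synthetic panel, train all six models on
2000–2020 and score the 2021 forecasts:

```yaml
# run.yaml
synthetic: {n_counties: 200, n_years: 22, n_blocks: 10,
            high_block: "02", low_block: "05", seed: 7}
train_window: [2000, 2020]
target_year: 2021
grids:
  random_forest: {n_estimators: [100], max_depth: [3, 5]}
  gradient_boosting: {n_estimators: [100], max_depth: [1, 3]}
  svm_rbf: {C: [1, 10], gamma: [0.1, 1]}
seed: 7
```

```sh
$ epidmd compare --config run.yaml --out out
INFO evaluation report:
            model     rmse  spearman   n
              dmd 2.049358  0.836368 200
           linreg 2.089366  0.823396 200
          svm_rbf 2.166828  0.827961 200
    random_forest 2.254537  0.808559 200
gradient_boosting 2.311697  0.789778 200
             holt 4.317972  0.594757 200
```

The generator adds Gaussian observation noise with standard deviation 2, so
an RMSE near 2 means a model has recovered the predictable signal almost
entirely; DMD's Spearman coefficient of 0.84 says it orders counties by
risk nearly correctly. Holt, fit per county on 21 noisy points, chases the
noise and trails the pooled models.

`epidmd fit-dmd --config run.yaml --out out` writes the spectral
diagnostics. The leading spectrum row,

```
re,im,magnitude,frequency,growth,inside_unit_circle
0.970398,0.0,0.970398,0.0,-0.030049,True
```

is the dominant steady mode: a real eigenvalue at 0.97, i.e. the overall
incidence level decays about 3% per year — and `dominant_mode.csv` gives
its per-county magnitudes, in which every county of the inflated block
("02", the high-incidence pseudo-state) outranks all others.

The same pipeline runs on real data: point `input:` at a wide CSV
(`fips,2000,...,2021`), or use `epidmd.io_panel.read_long_csv` /
`assemble_panel` / `filter_complete` for long-format registry extracts
(counties with any missing year are dropped, complete-case style, and
reported by FIPS).

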