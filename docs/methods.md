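# Methods

## Model

The panel is treated as snapshots of a linear dynamical system: x_k ∈ R^n
holds every county's age-adjusted incidence rate in year k, and consecutive
snapshots are assumed related by a fixed linear propagator, x_{k+1} ≈ A x_k.
Exact DMD identifies the leading spectrum of A without forming it:

1. X1 = [x_1 … x_{m-1}], X2 = [x_2 … x_m];
2. reduced SVD X1 ≈ U Σ V* truncated at rank r;
3. Ã = U* X2 V Σ⁻¹ (r×r), eigendecomposition Ã W = W Λ;
4. modes Φ = X2 V Σ⁻¹ W, amplitudes b = argmin ‖Φ b − x_1‖₂;
5. prediction x_k ≈ Re(Φ Λ^{k-1} b).

The linearity assumption is the method's main commitment: it represents the
panel as a superposition of spatial patterns each decaying/oscillating
geometrically. Slowly trending rate panels fit this well; strongly
intermittent dynamics would not.

Conventions the algebra leaves open, fixed here for determinism:

- **Amplitudes** are fitted to the *first* snapshot by least squares, the
  standard exact-DMD convention.
- **Mode normalization**: Φ columns are scaled to unit Euclidean norm with
  the scale absorbed into b, so per-county magnitudes are comparable across
  runs and ranks.
- **Eigenvalue order**: |λ| descending, ties by phase ascending.
- **Numerical rank**: singular values above max(n, m−1)·ε·σ₁; `rank="full"`
  uses it, and requesting more raises an error naming the attainable rank.
- **Rank truncation happens in (real) SVD space**, so a truncated spectrum
  may contain an unpaired complex eigenvalue; `predict` returns the real
  part, and the real-output guarantee (|Im| < 1e-8·‖x‖) is asserted only
  for conjugate-closed spectra.
- **Dominant steady mode**: among eigenvalues with |arg λ| < 1e-6 (no
  oscillation), the one maximizing |b_j|·|λ_j|^{m−1} — the amplitude still
  alive at the end of the training window — is reported; if none exists the
  error suggests loosening the tolerance rather than silently picking an
  oscillatory mode.

## Comparator models

All comparators share one protocol: tune on years 1..L → year L+1, then
apply the trained model to the window shifted one year forward to forecast
the held-out year.

- **Holt (exponential smoothing with additive trend)**, per county:
  l_t = αy_t + (1−α)(l_{t−1}+b_{t−1}), b_t = β(l_t−l_{t−1}) + (1−β)b_{t−1},
  initialized l₁ = y₁, b₁ = y₂ − y₁; forecast l_m + b_m. Default α = 0.2
  (a conventional weight for slowly trending public-health series) and
  β = 0.1; a per-county β chosen by in-sample one-step SSE over a 20-point
  grid is available (`holt_forecast_optimized_beta`) but off by default to
  keep runs deterministic and cheap.
- **Lagged linear regression**: OLS of the target year on an intercept plus
  the L prior years, counties as rows; minimum-norm solution with a
  rank-deficiency flag when the design is singular.
- **Random forest / gradient boosting / RBF-SVR** (scikit-learn) on the
  same lagged design. Hyperparameters come from an exhaustive grid scored
  by *training-set* RMSE — deliberately not cross-validation, because the
  training-RMSE criterion is the protocol this pipeline standardizes on;
  the full grid table is returned so the overfitting risk is auditable, and
  ties go to the first cell in enumeration order. Defaults: RF trees
  {100, 300, 500} × depth {3, 5, 10}; GBM trees {100, 300, 500} ×
  interaction depth {1, 3, 5} (mapped to tree `max_depth`); SVR cost
  {0.1, 1, 10, 100} × gamma {0.1, 1, 10, 100} with features standardized to
  zero mean / unit variance so absolute gamma values are meaningful.

Treating counties as exchangeable rows of one supervised design is the
largest interpretive choice in the comparator suite: it pools spatial
replicates to estimate one temporal map, which is what makes the pooled
models so much more noise-robust than the per-county Holt recursion.

## Synthetic data

`GeneratorConfig` defaults define the study conditions: n = 1,000 counties,
m = 22 annual snapshots, generating spectrum {0.97, 0.9e^{±0.6i}} (one slow
real decay ≈ 3%/year plus one oscillatory pair, the minimal spectrum
exhibiting every diagnostic), mean initial level 65 per 100,000, additive
i.i.d. Gaussian observation noise with sd 2 (rate units), 50 pseudo-states
of 20 counties with block-structured FIPS codes, the dominant-mode loading
of block "21" inflated 3× and of block "06" deflated 0.5× (the
high-incidence-state / low-incidence-state geography), and no missingness
unless `missing_fraction > 0`.

Two deliberate design points:

- **The positive baseline lives inside the dominant mode** (all-positive
  loadings whose amplitude sets the mean level), not in an additive
  constant. A constant offset is itself a λ = 1 mode; adding one would
  raise the noise-free rank to r_true + 1 and break exact eigenvalue
  recovery at rank r_true. An explicit `offset` parameter (default 0)
  exists for experiments that want a literal shift.
- **Noise is observational, not process noise**, and rates are *not*
  clipped at zero by default: clipping is a nonlinearity that would poison
  the recovery oracles. Under the default configuration the noise-free
  rates stay non-negative and the noise floor (~29 per 100,000 in the
  deflated block) keeps noisy rates positive in practice; `clip_negative`
  is an opt-in realism flag.

What the generator does **not** emulate: covariates (smoking, demographics),
spatial autocorrelation beyond block loadings, reporting-delay dynamics, and
any nonlinearity. Passing recovery tests therefore demonstrates algorithmic
correctness on data satisfying the model's assumptions, not forecasting
skill on real registry data, where the linear-dynamics approximation is
exactly the hypothesis under study.

`inject_missing` blanks 1–3 random years in ⌊fraction·n⌋ randomly chosen
counties (seeded), logging their FIPS codes, so the complete-case filter
(`filter_complete`: drop any county with any missing year, no imputation)
can be checked against the injection log exactly.

## Numerical choices and degenerate inputs

- Missing-value sentinels on input: empty cell, `NA`, `^`, `*` (registry
  suppression marks); negative rates are rejected at parse time as a
  corruption signal.
- Duplicate (fips, year) records that agree are de-duplicated; conflicting
  duplicates raise an integrity error naming the pair.
- A zero snapshot matrix raises a degenerate-input error; m = 1 snapshot an
  insufficient-data error; Spearman on a constant vector an
  undefined-metric error (a constant forecaster is a bug worth surfacing,
  not a 0 to record).
- Panels of exactly linear county trends make the propagator's unit
  eigenvalue defective (a Jordan block), which an eigendecomposition-based
  predictor can only approximate; the one-step forecast error grows with
  the training window and is ~1e-7 for 6-year windows — the regime the test
  suite exercises.

## Problem sizes

The test suite and acceptance script run the study conditions at full panel
size (1,000 × 22): noise-free recovery once, the dense-pseudoinverse oracle
on 100 random panels up to 8 × 10, spectral diagnostics over 20 seeds,
dominant-mode geography over 10 seeds, and the six-model benchmark once,
with one-or-two-candidate grids per hyperparameter for the tree/kernel
models (the package's benchmark-scale default; the full grids remain the
library defaults). Unit tests use 40–200-county panels.

## Known limitations

- Exact DMD only: no optimized DMD, no control inputs, no time-delay
  embedding, no streaming updates; the n×n operator is never materialized.
- One-step-ahead forecasting only; no prediction intervals.
- The grid-search criterion (training RMSE) can overfit flexible families;
  a cross-validation option is a natural extension but is not the default
  protocol here.
- Choropleth rendering is out of scope; the dominant-mode table is emitted
  join-ready, keyed by FIPS.
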