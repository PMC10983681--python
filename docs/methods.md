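# Methods

`bloodhts` forecasts monthly blood-donation counts organized in a strict
tree: the national total at the root, donor gender at level 1, and the ABO
blood group within each gender at the bottom (11 nodes, 8 of them
bottom-level). This note records the models, the numerical choices and the
limits of what the test suite demonstrates.

## The hierarchy and coherence

With `m` bottom nodes and `n` total nodes, the summing matrix `S` (n x m,
entries 0/1) maps bottom values to the full node vector, `y = S y_b`. A
set of forecasts is *coherent* when it lies in the column space of `S` —
upper forecasts equal the sums of their descendants. Node order is fixed
everywhere (root, level-1 left-to-right, bottom left-to-right) so matrices
and CSV columns are reproducible bit for bit.

Only strict balanced trees are accepted. Grouped or crossed structures
(e.g. blood group x region as parallel disaggregations) and unbalanced
trees are rejected with explicit errors; supporting them would change the
construction of `S` and the meaning of the top-down schemes.

Coherence checking is report-only, with default absolute tolerance 1e-6
for float series (floating-point summation) and 0 for integer input.
Aggregation and the check use the same `S`-row summation, so
`aggregate -> check_coherence(tol=0)` passes exactly.

## Base forecasters

Each node series is forecast independently; reconciliation happens
afterwards.

**Seasonal ARIMA with automatic order selection.** Estimation uses
statsmodels' SARIMAX (exact Gaussian likelihood, stationarity and
invertibility enforced). The order search is this package's own, in the
spirit of the Hyndman–Khandakar algorithm:

1. seasonal differencing order `D in {0,1}` from an STL seasonal-strength
   statistic, `1 - Var(remainder)/Var(seasonal + remainder)`, with
   threshold 0.64;
2. ordinary differencing order `d` by repeated KPSS level tests at 5% on
   the (seasonally differenced) series, capped at 2;
3. a stepwise AICc search over `p,q <= 3`, `P,Q <= 1`: four standard
   starting models, then +/-1 neighbourhood moves until no improvement.
   `stepwise=False` runs the exhaustive grid instead.

A constant is included only when `d + D = 0`; both search modes share the
policy, so the stepwise-vs-exhaustive agreement test compares like with
like. Note SARIMAX's constant is the ARMA-equation intercept, so the
implied mean is `intercept / (1 - sum AR)`; for a selected (0,0,0) model
it is the sample mean directly. Constant series short-circuit to a
(0,0,0) model with the constant as intercept; fitting is deterministic
(no random restarts), so forecasts are seed-invariant.

Forecasting re-anchors the frozen parameter vector to any history via a
Kalman-filter pass, which keeps `fit` and `forecast` cleanly separated and
lets the model refit on the full sample forecast beyond it.

**Holt-Winters / ETS.** Additive trend with additive or multiplicative
monthly seasonality, estimated by statsmodels' `ExponentialSmoothing`
(deterministic optimizer, smoothing parameters in [0,1]); mode "auto" fits
both where admissible and keeps the lower AICc. We deliberately reuse the
library optimizer rather than hand-rolling a Nelder-Mead on
(alpha, beta, gamma): it satisfies the same contract and is better tested.
The end-of-sample state (level, trend, last seasonal cycle) is extracted
and frozen; multiplicative seasonal indices are renormalized to average 1
with the scale folded into level and trend, which changes no forecast but
makes states comparable across series. Point forecasts are closed-form:
`(level + h * trend) op seasonal_index(h)`.

Negative point forecasts are never clipped before reconciliation —
clipping would break the linear-algebra identities; rounding or flooring
is an export-time option only.

## Reconciliation

Let `yhat(h)` be the stacked base forecasts at step `h`.

* **Bottom-up (BU):** keep the bottom block, rebuild uppers via `S`.
  Bottom forecasts are conserved exactly; upper base forecasts are ignored.
* **Top-down, average historical proportions (TDHP):**
  `p_i = mean_t(Y_{i,t} / Y_t)` against the root total (the printed
  formula). A `within_parent=True` variant multiplies time-averaged
  within-parent shares down the ancestor chain; the two agree when shares
  are constant. Requires a strictly positive root history.
* **Top-down, proportions of historical averages (TDHA):**
  `p_i = mean_t(Y_{i,t}) / mean_t(Y_t)` — the standard reading of the
  scheme's name, which is stated without a formula in the source
  methodology.
* **Top-down, forecast proportions (TDFP):** per step,
  `p_i = prod over ancestors a of ( yhat_child / sum of sibling yhats )`,
  recomputed from that step's base forecasts. The telescoping product
  makes each step's proportions sum to 1 exactly; a zero sibling-group sum
  raises rather than silently renormalizing.
* **Optimal combination (OC):** per step solve
  `min_b (yhat - S b)' W (yhat - S b)` and report `S b`. Default `W = I`
  (OLS) — the estimated-covariance weighting is approximated away exactly
  as in the source methodology, since the error covariance of the full
  hierarchy is not identifiable from one holdout; a positive diagonal `W`
  is exposed for variance weighting. With OLS this is the orthogonal
  projection `S (S'S)^{-1} S' yhat`: idempotent, and the identity on
  already-coherent inputs. For a strict tree `S` has full column rank, so
  the normal equations are solved directly (no pseudoinverse needed).

Trace-minimization (MinT) with an estimated error covariance is out of
scope.

## Evaluation and selection

MAPE is `100/m * sum |y - yhat| / y`; zero actuals raise an error rather
than being skipped. (The source tables are only reproducible under this
absolute-value, percentage reading.) The evaluation design holds out the
last 12 months by default — matching the annual forecasting cadence —
fits each base model per node on the history, reconciles with each
scheme, scores every node, and appends an Average row (arithmetic mean
over nodes). `select_best` picks the column with the smallest average
MAPE; ties break on the declared column order (ETS block then ARIMA
block, each BU, TDFP, TDHA, TDHP, OC) and are logged. A single split is
the default; the table is recomputed per call, so rolling-origin designs
can be layered on top but are not claimed.

MAPEs are reported to 2 d.p.; selection compares unrounded values.

## Synthetic registry generator

The generator emulates the statistical structure of a national donation
registry so every stage is testable without the (undeposited) source data.
Bottom node (group g, gender x) at month t:

    base_total * share_x * share_g * seasonal(month) * (1 + slope * t) * eps_t

with defaults: 144 months from 2007-01; gender shares M 0.54 / F 0.46;
group shares O 0.54 / A 0.24 / B 0.18 / AB 0.04; base monthly total 5265
(consistent with the per-group monthly means of the emulated registry);
multiplicative seasonal indices +15% in April, August and December
(school-holiday months) compensated to average exactly 1 — the source
names the months but not magnitudes, so 15% is a single fixed choice of a
plausible holiday lift; slope -0.0005/month (a mild decline, ~ -7% over
12 years, matching the reported gradual decrease); and mean-one lognormal
noise with sigma 0.08, keeping counts positive with mild right skew.
Upper levels are built by exact aggregation, so output is coherent by
construction and deterministic given the seed.

The shock injector multiplies bottom values in a window by
`1 - magnitude` (default 0.40, the reported pandemic-period collapse),
optionally ramping linearly back to 1, and re-aggregates; coherence is
preserved exactly.

What the generator does **not** emulate: donor-level behaviour (return
intervals, lapsing), cross-node correlation beyond the shared seasonal
and trend factors, heteroskedasticity across the calendar, and the
platykurtic noise of the real registry (lognormal noise is mildly
leptokurtic instead; the seasonal mixture brings the marginal kurtosis
down but it is not calibrated). Passing tests therefore demonstrate
correctness of the machinery and qualitative reproduction of the study's
phenomena (method ranking behaviour, shock-induced accuracy collapse),
not quantitative agreement with the registry's published error tables.

## Problem sizes and numerical choices

The default study conditions are used throughout: 144-month histories,
12-month holdout, 60-month forecast horizon, 11 nodes. The stepwise
search evaluates ~15-30 SARIMAX fits per node; a full two-model pipeline
is a few minutes of CPU. The stepwise-vs-exhaustive agreement check runs
at season length 4 with bounds p,q <= 2, P,Q <= 1 (n = 80), where the
exhaustive oracle is tractable; agreement is 9/10 seeded series, the
stepwise walk occasionally stopping at a local AICc optimum, which is the
documented behaviour of this class of search. AR(1) parameter recovery
uses n = 500 with 20 replicates; the selected order includes p >= 1
essentially always, while the leading AR coefficient lands within +/-0.1
of the truth in roughly 80-100% of replicates depending on the seed
block (measured 82/100 over a wide seed range), because AICc sometimes
prefers an ARMA(1,q) whose extra MA terms displace the AR estimate
slightly — the familiar behaviour of information-criterion selection,
not an estimation failure. Optimizer determinism makes every reported
number reproducible bit for bit given the seed.

Degenerate inputs: constant series bypass both fitters with exact
degenerate states; series shorter than 3 seasonal cycles (ARIMA) or 2
cycles (ETS) are rejected; multiplicative ETS requires strictly positive
values; failed SARIMAX candidates score AICc = +inf and drop out of the
search rather than aborting it.

## Known limitations

* Point forecasts only — no prediction intervals, no probabilistic
  reconciliation.
* OC uses OLS (or user-supplied diagonal) weights, not MinT.
* The top-down schemes assume a strictly positive root history; series
  with structural zeros need preprocessing.
* Automatic order selection is a heuristic; it recovers simple dynamics
  reliably (tested) but is not guaranteed to find the global AICc optimum.
* The generator's parameters are fixed study conditions, not fitted to
  any registry; conclusions about real data require real data.
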