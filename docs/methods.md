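# Methods

This note documents the modeling choices, defaults, and limitations of
`graincast`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Extreme temperature event climatology

A cell's heatwave threshold q_hw is the empirical 90th percentile (linear
interpolation between order statistics, `numpy.quantile(..., method="linear")`)
of **all** daily maximum temperatures pooled over the base period
(default 1981–2010). The coldwave threshold q_cw is the 10th percentile of
daily minima. A calendar-day moving-window climatology is deliberately out
of scope: the pooled-CDF reading keeps a single threshold per cell and makes
the calibration property exact (the fraction of base days strictly above
q_hw is ≤ 0.10 plus at most one order-statistic step).

Events are maximal runs of ≥ `min_run` (default 3) consecutive days with
strict exceedance (tasmax > q_hw, respectively tasmin < q_cw). Events never
span calendar years: annual frequency is defined per year, and a run crossing
Dec 31 counts in a year only if its within-year length still reaches
`min_run`. The calendar is 365-day no-leap throughout (matching the common
GCM convention and avoiding leap-day special cases).

**A false-looking invariant, documented.** Annual event *counts* are not
monotone under uniform warming with thresholds fixed: adding exceedance days
can merge two qualifying runs into one longer run, reducing the count
([T,T,T,F,T,T,T] holds two events; filling the gap leaves one). The monotone
quantity is the number of days inside qualifying events, provided by
`count_event_days_columns` and verified by the unit suite. One acceptance
test intentionally keeps the count-level statement and fails, as a permanent
record of the distinction.

Threshold downscaling to scenario resolution is bilinear interpolation
restricted to the source cell-center hull (extrapolation raises). The
synthetic scenario grid is constructed as a strict interior refinement
(every other node coincides with an observation center), so the restriction
costs nothing.

## Convolutional autoencoders

Two architectures, one trained instance per climate variable (4 total):

* **spatial** (annual `hw_freq`, `cw_freq` fields): Conv2d(1→8) → ReLU →
  Conv2d(8→16) → ReLU → flatten → dense → 8 codes.
* **spatio-temporal** (monthly `tas`, `pr` as (12, H, W) calendar-year
  blocks): Conv3d(1→8) → ReLU → Conv3d(8→16) → ReLU → Conv3d(16→32) → ReLU
  → flatten → dense → 8 codes.

All convs share kernel 3, stride 2, padding 1; weights use He initialization.
The decoder is a small dense network (8 → 64 → field, ReLU between): the
conv stack is what extracts spatial structure for the *encoder*, while the
decoder only needs to score reconstructions, and a dense decoder keeps the
hand-written backpropagation small and fast. Training minimizes mean squared
reconstruction error with Adam (lr 1e-3, batch 16); inputs are z-scored per
variable over the training set first, since MSE across variables with
different units is otherwise meaningless. Everything is plain numpy, so
training is bit-deterministic given `random_state`; the conv forward/backward
passes are gradient-checked against central differences in the test suite.

Per-province fields are cropped to the province bounding box, masked outside
it, and zero-padded to the union crop shape so a single architecture serves
all provinces. Encoders are trained on observation-period fields only;
scenario fields are first interpolated back onto the observation axes
(the pipeline normalizes all gridded inputs "to a uniform resolution" before
encoding), then encoded with the frozen observation-fitted weights.

Desk-scale defaults (epochs 60 in the pipeline driver, 200 in the estimator;
channel widths 8→16 and 8→16→32; hidden 64) are engineering choices — the
architecture contract is only the layer counts, ReLU placement, dense head,
and the 8-dimensional code.

## Case table and random forest

Each province-year case is 36 features: min-max-normalized SownArea,
PrimInd, MechPower; the raw time dummy dt (years since the first observation
year); and 8 codes for each of hw_freq, cw_freq, tas, pr, in a fixed,
documented column order. The target (production, tons) stays in natural
units — MAPE and the Gamma deviance are scale-free, and normalizing the
target would buy nothing. Min-max transforms are recorded and reused
verbatim on projection inputs.

The 80/20 split is random over province-year keys (seed-reproducible,
position-independent); the test share is ceil(0.2·n), so 192 cases give
153/39. Hyperparameters are selected by 5-fold cross-validated MAPE over a
cartesian grid (`n_estimators`, `max_depth`, `min_samples_split`,
`min_samples_leaf`, `ccp_alpha`); exact ties break toward the smaller, then
shallower forest. The CV table (mean MAPE and Gamma deviance per
combination) is exported as the search surface. MDI importances are summed
over each climate variable's 8 codes; the aggregation conserves the total.

## Benchmarks

**B1-FGLS**: ln(production) on [1, ln x₁, ln x₂, ln x₃, dt, tas, pr,
hw_freq, cw_freq], with the economic levels entering raw (they are strictly
positive; min-max-normalized values hit exact zeros and cannot be logged)
and climate in levels (temperatures and frequencies may be ≤ 0). Two-step
FGLS: OLS, then log squared residuals regressed on the fitted values, then a
weighted refit with weights 1/exp(fitted variance). Rank deficiency raises
an error naming the collinear columns. Predictions are exp of the linear
predictor (no smearing correction; the benchmark is compared on the same
scale-free metrics as the primary model).

**B2-RF**: identical split seed, folds, and search grid as the primary
model, but each climate variable is reduced to its province spatial mean —
8 features. The difference against the 36-feature model isolates the value
of spatial structure.

## Projection

Economics (including dt) are frozen at the last observed year; projections
therefore move only with climate. Ensemble aggregation uses the across-member
median and 25th/75th percentiles per year; time series are summarized by
non-overlapping 4-year block means (2021–2024, …), which conserve the series
mean over complete groups. Members are ranked by the plain sum of projected
heatwave frequency over all cells and years — any monotone transform yields
the same halves — and split top/bottom 50% (odd counts put the extra member
in "higher"; ties break by member id). The HW–CW trade-off fits least-squares
slopes in both directions on pooled cell-years; the product of the two slopes
equals r². The temperature-anomaly regression drops points beyond 3
MAD-based robust standard deviations from an initial fit, once, then refits.

## Synthetic world

Daily temperature is a latitude-graded seasonal harmonic (peak mid-July,
amplitude 12 °C) plus a linear warming trend (0.25 °C/decade) plus
stationary AR(1) noise (marginal sd 2 °C, lag-1 coefficient 0.7); tasmax and
tasmin sit ±5 °C around the mean cycle. Warm/cold runs of chosen cells,
start, length and magnitude can be stamped in, and every injected run whose
magnitude clears the local threshold is recovered by the detector (tested).
Monthly precipitation follows a monsoon-like profile (peak ≈ 180 mm in
June–July) with multiplicative log-normal noise; monthly temperature is the
same harmonic at monthly resolution. Economic series use multiplicative
log-normal noise around stylized trends: primary-industry employment falls
~65% over the window, machinery power roughly triples, sown area varies
slowly — the qualitative shape of provincial yearbook series.

Production follows a Cobb-Douglas core with a climate modifier linear in the
per-province climate summaries:

    Y = A·x₁^0.9·x₂^0.10·x₃^0.15·e^(0.005·dt) ·
        max(0.05, 1 − 0.010(tas − 16) + 5·10⁻⁵(pr − 1000) − 0.020·hw − 0.010·cw) + ε

with ε ~ N(0, 30 t). Sown area dominates by construction, which is what
makes the importance-recovery experiment meaningful. Pseudo-GCM ensembles
put member m at a fixed temperature offset (evenly spaced over ±0.5 °C,
ordered by member index — known heatwave-propensity ordering) plus a
scenario-specific linear warming (0.10 / 0.25 / 0.45 / 0.60 °C per decade
for the four scenario ids), on the 2×-finer scenario grid.

**What a green test does and does not establish.** The generator reproduces
structural features — seasonal cycles, autocorrelated extremes, trending
economics, a known response — not the magnitudes or spatial textures of any
real region. Green recovery tests establish that the pipeline can extract a
signal it was constructed to contain; they say nothing about real-world
yield sensitivity, and the default-world projection trend can even be
positive (warm-year code patterns correlate with the rising observed
production trend). The directional-recovery test therefore uses a world with
the heatwave penalty isolated.

## Numerical conventions

* Quantiles: linear interpolation between order statistics, everywhere.
* Explained variance: population (1/n) variance convention.
* Gamma deviance: summed (not averaged) form, n × scikit-learn's
  `mean_gamma_deviance` (cross-checked in tests).
* Strict inequalities for exceedance on both sides.
* All randomness flows from one seed through named integer stream ids
  (`numpy.random.SeedSequence`), so stages are independently reproducible.
* NetCDF is written with the scipy (NetCDF3) engine; temperatures declared
  in K are converted to °C on read.

## Known limitations

* The decoder being dense (not transposed-conv) means reconstructions are
  not translation-equivariant; codes may use absolute position. For
  province-cropped, zero-padded fields this is acceptable (position is
  meaningful), but it would not transfer to sliding-window use.
* FGLS uses a single-step variance model (log r² on fitted values); no
  iteration to convergence.
* Per-province cropping assumes rectangular provinces; real administrative
  shapes would need true masks (the masking path exists, the synthetic
  geometry just never exercises ragged shapes).
* The projection driver interpolates scenario-resolution frequencies back to
  the observation grid before encoding; sub-observation-scale extremes
  patterns are therefore smoothed before the encoder sees them.
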