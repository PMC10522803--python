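# Methods

This note documents the statistical models, defaults, and design choices in
chetrack, and what the synthetic-data experiments do and do not demonstrate.

## Catastrophic health expenditure and its drivers

A household is counted as incurring catastrophic health expenditure (CHE)
when its out-of-pocket (OOP) health spending **strictly exceeds** a threshold
share τ of its consumption expenditure (τ = 0.10 by default, 0.25 as the
sensitivity threshold). A household spending exactly τ·C is *not* flagged.
Amounts reported over different recall windows are rescaled linearly to a
common annual period (365 days) before the ratio is formed; since the ratio
is invariant to the common period, this choice affects only reported
expenditure levels, which may additionally be multiplied by a configured
purchasing-power-parity scalar at reporting time.

Population quantities are expansion-weighted. Weighted proportions carry a
design-adjusted binomial standard error using the Kish effective sample size
`n_eff = (Σw)²/Σw²`; this approximates the design effect of unequal weights
without stratum/PSU identifiers, which household-budget public files often
lack. When cluster identifiers are available, a between-cluster variance of
the ratio estimator is provided instead.

Monthly visit rates support two recall conventions: *annual recall* (visits
over the past year are dated by month; the denominator is the full weighted
sample for every month) and *monthly recall* (each month is an independent
cross-section; the denominator is that month's weighted respondents). Months
with zero denominator propagate as missing, never as zero. The
private-sector label set is configurable per country (pharmacies count as
private in both bundled conventions). Relative use is the arithmetic
difference of monthly rates against the most recent pre-shock survey year,
in percentage points — this differencing nets out seasonality shared by the
two years.

## Counterfactual ensemble forecast

Four autoregressive forms are fitted per annual series by OLS: level on
lag-level and first difference on lagged difference, each with and without a
constant. Multi-lag and moving-average models are out of scope — the series
have 6–17 points. Model performance is measured by rolling-origin one-step
out-of-sample RMSE over the last `min(3, n−6)` observed points.

The ensemble forecast for the year after the series ends draws, by default,
1000 paired samples: draw *i* combines coefficients sampled from one model's
OLS coefficient distribution (models allocated equally across draws;
inverse-RMSE weighting is available) with a perturbed copy of the series in
which each point receives normal noise at its sampling standard error. Draws
on the proportion scale are clamped to [0, 1] (clamp counts are logged); the
summary is the mean and the 2.5th/97.5th percentiles. Residual innovation is
*not* added by default — the interval describes the predicted mean level —
but can be enabled. An observed value is declared **different** from the
counterfactual when the two closed 95% intervals are disjoint (touching
endpoints overlap).

Calendar gaps in sparse series (e.g. a series observed in 2004 and then
2010–14) are treated as consecutive steps in the lag structure, with a
logged warning; the alternative (dropping non-adjacent pairs) would leave
some series unfittable.

Two properties of this machinery are worth stating plainly:

* **Small-sample AR bias.** The OLS slope of an AR(1) with intercept is
  biased downward by roughly (1+3b)/n; at n = 16 this is ≈ 0.26 for b = 0.8
  and ≈ 0.08 for b = 0.1. Slope recovery to a tight bias budget is therefore
  only demonstrable for weakly persistent series; for persistent series the
  bias is an estimator property, not an implementation defect. The
  acceptance script reports the measured bias at both b = 0.1 and b = 0.8.
* **Power of the non-overlap rule.** Two independent 95% intervals separate
  only when the shock exceeds ≈ 2×1.96 combined SDs, so a shock of exactly
  4 forecast-SDs sits at the decision boundary (~50% power). The calibration
  study uses a shock of 6–12 forecast-SDs, where detection is reliable; the
  rule is deliberately conservative, trading power for a very low
  false-alarm rate (<2% measured).

## Interrupted time series

The segmented regression `Y = β1 + β2·month + β3·I(post) + β4·I(post)·month`
is fitted by OLS with Newey-West (Bartlett-kernel) HAC standard errors, no
small-sample correction, so lag 0 reduces exactly to HC0. The month count is
centred at the first post-intervention month, so β3 is the jump at the
intervention itself; any other origin is an equivalent reparameterisation of
(β1, β3) leaving fitted values, β2 and β4 unchanged. The post indicator
switches on at the first full month after stay-at-home orders (April for
orders issued mid/late March). Pooled biennial designs (e.g. a survey run in
2018 and 2020 but not 2019) take an extra year intercept for the later year
so β3 does not absorb the secular two-year drift. Missing months are dropped
with logging; 95% CIs use 1.96 by default with a small-sample t alternative
behind a flag.

Default Newey-West truncation is lag 1. A caveat measured during
development: on 24-month series with serially *independent* noise, lag-1 HAC
intervals at the normal critical value cover a true level shift in only
≈ 87% of replicates — the Bartlett cross-terms add small-sample downward
bias to the SE without any autocorrelation to correct. With the truncation
matched to independent noise (lag 0) coverage is ≈ 90–91%, and ≈ 91–94% with
t critical values. The simulation studies therefore evaluate coverage at
lag 0 with t critical values; on real monthly series, where serial
correlation is plausible, the lag-1 default remains the safer choice, but
its intervals on T ≈ 24 series should be read as approximate.

## Synthetic data

The generators emulate the features the estimators rely on, with all
ground-truth parameters returned to the caller:

* **Household surveys**: consumption is lognormal (location 9.2, scale 0.7
  on the log scale — median ≈ 10,000 currency units/year); OOP is a
  zero-inflated Beta share of consumption (zero-probability 0.35, Beta(0.8,
  12)), guaranteeing 0 ≤ OOP < consumption and yielding a CHE(10%) rate
  near 0.1; weights are Gamma with CV 0.5, mean-normalised then expanded.
  Amounts are emitted on their configured recall periods, so downstream
  estimation must rescale.
* **Annual CHE series**: the true path is AR(1), p_t = 0.02 + 0.8·p_{t−1} +
  N(0, 0.004²) (stationary mean 0.10, persistence typical of a slow-moving
  national rate), 2004–20 by default, with an optional additive final-year
  shock, clamped to (0, 1) after shocks. Per-year household tables make the
  weighted CHE estimate unbiased for the path value; a microdata-free mode
  draws the estimate directly at the analytic Kish standard error for cheap
  replicate studies.
* **Monthly utilisation**: a single sinusoid seasonal around the baseline
  rate, an additive level shift from the intervention month, a trend change
  accumulating after it, i.i.d. normal noise, clamped to [0, 1].

What passing these tests shows — and does not. The generators verify the
estimators, the uncertainty propagation, and the decision rules under known
truth. They do not mimic multistage stratified sampling, nonresponse,
questionnaire structure, item nonresponse in expenditure modules, or
serially correlated month-to-month noise; coverage statements on real survey
data therefore inherit the usual caveats about unmodelled design effects.

## Numerical choices and degenerate inputs

Simulation sizes were chosen to make every study run comfortably on a
single CPU: 500 replicates for coverage/bias studies, 300 for power, 1000
ensemble draws, ~1500–2000 households per synthetic survey year. Exact
checks use tolerances 1e-10–1e-12; Monte-Carlo assertions use bounds several
MC standard errors wide. Rank-deficient AR designs (zero-variance
regressor) are accepted only when the minimum-norm solution is exact (a
constant series), with zero coefficient covariance; otherwise they raise a
degenerate-fit error. Unfittable ensemble members are dropped with a
warning; an ensemble with no members is an error. ITS designs are checked
for full column rank and raise naming the columns otherwise. All stochastic
operations take an explicit seed; there is no hidden global random state,
and identical (config, seed) reproduce byte-identical pipeline outputs.
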