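"""Interrupted time-series (ITS) analysis of monthly health-care series.

Estimates the level shift and trend change in a monthly outcome (relative
health-care use in percentage points, or the private-sector share of
visits) when stay-at-home orders began, via the segmented OLS regression

    Y_t = b1 + b2*month + b3*I(post) + b4*I(post)*month + e_t

where ``month`` is a consecutive count over the retained observations,
``I(post)`` switches on at the first full post-intervention month, and the
interaction carries the post-period trend change.  ``b3`` is the level
shift at the intervention and ``b4`` the change in monthly trend.  Standard
errors are Newey-West (HAC, Bartlett kernel) to absorb serial correlation
in the short monthly series.

The month count is centred at the intervention by default, so ``b3``
measures the jump at the intervention month itself; any other origin is an
equivalent reparameterisation of ``b1`` and ``b3`` leaving fitted values,
``b2`` and ``b4`` unchanged.  When series from non-adjacent survey years
are pooled (e.g. a biennial survey contributing 2018 and 2020), an extra
year intercept can absorb the secular level difference between years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DataError, DesignError

logger = logging.getLogger(__name__)

Z95 = 1.96  # normal critical value for 95% intervals


@dataclass
class ITSDesign:
    """Design matrix and aligned outcome for the segmented regression."""

    y: np.ndarray
    X: pd.DataFrame  # columns: const, month, covid, covid_month [, year_*]
    kept_positions: np.ndarray  # original 1-based positions of retained rows
    intervention_position: int
    nw_lag: int = 1


@dataclass
class ITSResult:
    """Coefficients, Newey-West SEs and 95% CIs from a segmented regression."""

    params: pd.Series
    nw_se: pd.Series
    ci95: pd.DataFrame  # columns: lower, upper
    lag_used: int
    n_obs: int
    fitted: np.ndarray
    residuals: np.ndarray

    @property
    def beta3(self) -> float:
        """Level shift at the intervention (outcome units)."""
        return float(self.params["covid"])

    @property
    def beta4(self) -> float:
        """Post-intervention change in monthly trend (outcome units/month)."""
        return float(self.params["covid_month"])


def build_design(
    outcome_series,
    intervention_position: int,
    year_labels=None,
    dummy_years=None,
    nw_lag: int = 1,
) -> ITSDesign:
    """Build the segmented-regression design from a monthly outcome series.

    ``outcome_series`` is ordered; NaN months (zero-denominator months
    upstream) are dropped with a log message.  ``intervention_position`` is
    the 1-based index of the first post-intervention month.  With
    ``year_labels`` (one calendar year per observation) and ``dummy_years``,
    an indicator column is added per listed year to absorb between-year
    level differences in pooled designs.
    """
    y = np.asarray(outcome_series, dtype=float)
    n_total = len(y)
    if not (1 <= intervention_position <= n_total):
        raise DataError("intervention_position must fall inside the series")
    keep = ~np.isnan(y)
    if not keep.all():
        logger.info("dropping %d missing month(s) from the ITS design",
                    int((~keep).sum()))
    positions = np.arange(1, n_total + 1)[keep]
    y = y[keep]
    if y.size < 5:
        raise DataError("too few non-missing months for a segmented regression")

    month = positions - intervention_position  # 0 at the first post month
    covid = (positions >= intervention_position).astype(float)
    cols = {
        "const": np.ones(y.size),
        "month": month.astype(float),
        "covid": covid,
        "covid_month": covid * month,
    }
    if dummy_years:
        if year_labels is None:
            raise DataError("dummy_years requires year_labels")
        years = np.asarray(year_labels)[keep]
        for yr in dummy_years:
            cols[f"year_{yr}"] = (years == yr).astype(float)
    X = pd.DataFrame(cols)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise DesignError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} "
            f"columns {list(X.columns)})"
        )
    return ITSDesign(y=y, X=X, kept_positions=positions,
                     intervention_position=intervention_position, nw_lag=nw_lag)


def fit_ols(design: ITSDesign) -> tuple[np.ndarray, np.ndarray]:
    """Plain OLS solve; returns (coefficients, residuals)."""
    res = sm.OLS(design.y, design.X).fit()
    return res.params.to_numpy(), np.asarray(res.resid)

def newey_west_se(X, residuals, lag: int) -> np.ndarray:
    """Newey-West (Bartlett-kernel HAC) standard errors for an OLS fit.

    Sandwich ``(X'X)⁻¹ S (X'X)⁻¹`` with
    ``S = Γ₀ + Σ_{j=1..lag} w_j (Γ_j + Γ_j')``, ``w_j = 1 − j/(lag+1)`` and
    ``Γ_j = Σ_t e_t e_{t−j} x_t x_{t−j}'``.  No small-sample correction.
    ``lag=0`` reduces to the heteroskedasticity-robust (HC0) estimator.
    """
    X = np.asarray(X, dtype=float)
    e = np.asarray(residuals, dtype=float)
    n, k = X.shape
    if lag < 0 or lag >= n:
        raise DataError(f"lag must satisfy 0 <= lag < n_obs, got {lag} with n={n}")
    xe = X * e[:, None]
    S = xe.T @ xe  # Γ₀
    for j in range(1, lag + 1):
        w = 1.0 - j / (lag + 1.0)
        gamma = xe[j:].T @ xe[:-j]
        S += w * (gamma + gamma.T)
    bread = np.linalg.inv(X.T @ X)
    cov = bread @ S @ bread
    return np.sqrt(np.diag(cov))


def fit_its(
    outcome_series,
    intervention_position: int,
    lag: int = 1,
    year_labels=None,
    dummy_years=None,
    use_t: bool = False,
) -> ITSResult:
    """Fit the full segmented regression with Newey-West uncertainty.

    ``lag`` is the Newey-West truncation (default 1, suited to series of
    12–24 months).  With ``use_t=True`` the 95% CI uses the small-sample t
    critical value instead of 1.96.
    """
    design = build_design(outcome_series, intervention_position,
                          year_labels=year_labels, dummy_years=dummy_years,
                          nw_lag=lag)
    res = sm.OLS(design.y, design.X).fit(
        cov_type="HAC", cov_kwds={"maxlags": lag, "use_correction": False}
    )
    se = pd.Series(res.bse, index=design.X.columns)
    params = pd.Series(res.params, index=design.X.columns)
    if use_t:
        from scipy import stats as _st  # statsmodels already depends on scipy

        crit = float(_st.t.ppf(0.975, res.df_resid))
    else:
        crit = Z95
    ci = pd.DataFrame(
        {"lower": params - crit * se, "upper": params + crit * se},
        index=design.X.columns,
    )
    logger.info("ITS fit: n=%d, NW lag=%d, dropped=%d month(s)",
                design.y.size, lag,
                len(np.asarray(outcome_series)) - design.y.size)
    return ITSResult(
        params=params,
        nw_se=se,
        ci95=ci,
        lag_used=lag,
        n_obs=int(design.y.size),
        fitted=np.asarray(res.fittedvalues),
        residuals=np.asarray(res.resid),
    )


def extrapolate_reference_trend(reference_values, predict_positions) -> np.ndarray:
    """Extend a reference year's linear trend to later months.

    Fits an OLS line to the reference series (positions 1..len, NaN months
    dropped) and evaluates it at ``predict_positions`` on the same month
    axis — used to check whether later observed rates sit on the
    pre-existing secular trend.
    """
    ref = np.asarray(reference_values, dtype=float)
    pos = np.arange(1, len(ref) + 1, dtype=float)
    keep = ~np.isnan(ref)
    if keep.sum() < 2:
        raise DataError("need at least two non-missing reference months")
    slope, intercept = np.polyfit(pos[keep], ref[keep], 1)
    predict_positions = np.asarray(predict_positions, dtype=float)
    return intercept + slope * predict_positions
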