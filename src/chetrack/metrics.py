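"""Survey-weighted estimation of catastrophic health expenditure and its drivers.

Catastrophic health expenditure (CHE, SDG indicator 3.8.2) flags a household
whose out-of-pocket (OOP) health spending exceeds a threshold share —
conventionally 10%, with 25% as an alternative — of its total consumption
expenditure.  Population-level CHE is the expansion-weighted share of
households flagged.  This module also estimates the drivers that move CHE:
household insurance coverage, mean OOP and consumption expenditure, monthly
health-care visit rates per person, and the private-sector share of visits.

All estimators take plain pandas tables in the documented schemas (the
synthetic generators emit the same schemas) and return tidy ``SeriesPoint``
records with design-adjusted standard errors.  Weighted proportions use the
Kish effective sample size n_eff = (Σw)² / Σw² to approximate the design
effect of unequal weights; optional cluster identifiers switch to a
cluster-robust variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

#: Common reporting period (days) to which recall amounts are rescaled.
ANNUAL_DAYS = 365

#: Default private-sector label sets per country convention.  Pharmacies are
#: private in both conventions.
PRIVATE_LABELS = {
    "mexico": frozenset({"private_clinic", "private_hospital", "pharmacy"}),
    "peru": frozenset({"private_consultation", "private_clinic", "pharmacy"}),
}


@dataclass(frozen=True)
class SeriesPoint:
    """One aggregated country-year metric value with its sampling uncertainty."""

    country: str
    year: int
    metric: str
    value: float
    se: float
    n: float

    def interval(self, z: float = 1.96) -> tuple[float, float]:
        return (self.value - z * self.se, self.value + z * self.se)


def series_to_frame(points: list[SeriesPoint]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in points])


def scale_to_common_period(amount, recall_days, target_days=ANNUAL_DAYS):
    """Linearly rescale an amount reported over ``recall_days`` to ``target_days``."""
    recall = np.asarray(recall_days, dtype=float)
    target = np.asarray(target_days, dtype=float)
    if np.any(recall <= 0) or np.any(target <= 0):
        raise DataError("recall and target periods must be strictly positive")
    amount = np.asarray(amount, dtype=float)
    if np.any(amount < 0):
        raise DataError("amounts must be nonnegative")
    out = amount * target / recall
    return float(out) if out.ndim == 0 else out


def flag_che(oop, consumption, threshold: float,
             oop_recall_days=None, consumption_recall_days=None):
    """True where OOP strictly exceeds ``threshold`` × consumption.

    Amounts on different recall periods are first rescaled to a common
    annual period; the ratio itself is invariant to that common period, so
    the choice only matters for reported expenditure levels.  The inequality
    is strict: a household exactly at the threshold is not flagged.
    """
    if not (0.0 < threshold < 1.0):
        raise DataError(f"threshold must lie in (0, 1), got {threshold}")
    oop = np.asarray(oop, dtype=float)
    consumption = np.asarray(consumption, dtype=float)
    if np.any(consumption <= 0):
        raise DataError("consumption must be strictly positive")
    if np.any(oop < 0):
        raise DataError("OOP spending must be nonnegative")
    if oop_recall_days is not None:
        oop = scale_to_common_period(oop, oop_recall_days)
    if consumption_recall_days is not None:
        consumption = scale_to_common_period(consumption, consumption_recall_days)
    return oop / consumption > threshold


def kish_neff(weights) -> float:
    """Kish effective sample size (Σw)² / Σw² of a weight vector."""
    w = np.asarray(weights, dtype=float)
    return float(w.sum() ** 2 / np.sum(w**2))


def _check_weights(weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise DataError("empty input")
    if np.any(w <= 0):
        raise DataError("weights must be strictly positive")
    return w


def estimate_weighted_proportion(flags, weights, clusters=None) -> tuple[float, float, float]:
    """Weighted proportion with a design-adjusted binomial standard error.

    Returns ``(value, se, n_eff)``.  By default the SE is the binomial
    sqrt(p(1-p)/n_eff) with the Kish effective sample size; when ``clusters``
    is given, a cluster-robust (between-PSU) variance of the ratio estimator
    is used instead and ``n_eff`` is the number of clusters.
    """
    w = _check_weights(weights)
    f = np.asarray(flags, dtype=float)
    if f.shape != w.shape:
        raise DataError("flags and weights must have equal length")
    value = float(np.sum(w * f) / w.sum())
    if clusters is None:
        neff = kish_neff(w)
        se = float(np.sqrt(max(value * (1.0 - value), 0.0) / neff))
        return value, se, neff
    clusters = np.asarray(clusters)
    resid = w * (f - value)
    totals = pd.Series(resid).groupby(clusters).sum().to_numpy()
    k = totals.size
    if k < 2:
        raise DataError("cluster-robust SE needs at least two clusters")
    var = k / (k - 1) * np.sum(totals**2) / w.sum() ** 2
    return value, float(np.sqrt(var)), float(k)


def estimate_weighted_mean(values, weights) -> tuple[float, float, float]:
    """Weighted mean with SE = weighted sd / sqrt(n_eff); returns (value, se, n_eff)."""
    w = _check_weights(weights)
    x = np.asarray(values, dtype=float)
    mean = float(np.sum(w * x) / w.sum())
    neff = kish_neff(w)
    var = float(np.sum(w * (x - mean) ** 2) / w.sum())
    return mean, float(np.sqrt(var / neff)), neff


def _annualised(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    cons = scale_to_common_period(table["consumption"], table["consumption_recall_days"])
    oop = scale_to_common_period(table["oop"], table["oop_recall_days"])
    return oop, cons


def estimate_che_rate(table: pd.DataFrame, threshold: float = 0.10,
                      country: str = "", year: int = 0) -> SeriesPoint:
    """Population CHE rate at ``threshold`` from a household table."""
    oop, cons = _annualised(table)
    flags = flag_che(oop, cons, threshold)
    value, se, neff = estimate_weighted_proportion(flags, table["weight"])
    metric = f"che{int(round(threshold * 100))}"
    return SeriesPoint(country, year, metric, value, se, neff)


def estimate_insurance_coverage(table: pd.DataFrame,
                                country: str = "", year: int = 0) -> SeriesPoint:
    """Weighted share of households in which any member is insured."""
    flags = table["insured"].astype(bool).to_numpy()
    value, se, neff = estimate_weighted_proportion(flags, table["weight"])
    return SeriesPoint(country, year, "insurance", value, se, neff)


def estimate_expenditure_means(table: pd.DataFrame, ppp_factor: float = 1.0,
                               country: str = "", year: int = 0) -> list[SeriesPoint]:
    """Weighted mean annual OOP and consumption expenditure, PPP-converted.

    ``ppp_factor`` is a configured scalar applied at reporting time only.
    """
    oop, cons = _annualised(table)
    w = table["weight"]
    points = []
    for metric, x in (("oop_mean", oop), ("consumption_mean", cons)):
        value, se, neff = estimate_weighted_mean(x, w)
        points.append(SeriesPoint(country, year, metric,
                                  value * ppp_factor, se * ppp_factor, neff))
    return points


def household_metrics(table: pd.DataFrame, thresholds=(0.10, 0.25),
                      ppp_factor: float = 1.0,
                      country: str = "", year: int = 0) -> list[SeriesPoint]:
    """All household-level metrics for one survey year, as tidy SeriesPoints."""
    points = [estimate_che_rate(table, t, country, year) for t in thresholds]
    points.append(estimate_insurance_coverage(table, country, year))
    points.extend(estimate_expenditure_means(table, ppp_factor, country, year))
    return points


def monthly_visit_rate(records: pd.DataFrame, convention: str) -> pd.Series:
    """Weighted health-care visits per person for each calendar month.

    Under ``annual_recall`` (visits over the past year are recalled, as in
    Mexico's survey) the denominator is the full weighted respondent count
    for every month; under ``monthly_recall`` (past-month recall, as in
    Peru's) each month's denominator is that month's weighted respondents.
    Months with a zero denominator yield NaN, never zero.
    """
    if convention not in ("annual_recall", "monthly_recall"):
        raise DataError(f"unknown recall convention {convention!r}")
    months = pd.Index(range(1, 13), name="month")
    visited = records["visited"].astype(bool)
    num = (
        records.loc[visited]
        .groupby("month")["weight"]
        .sum()
        .reindex(months, fill_value=0.0)
    )
    if convention == "annual_recall":
        denom_total = float(
            records.drop_duplicates("person_id")["weight"].sum()
        )
        denom = pd.Series(denom_total, index=months)
    else:
        denom = records.groupby("month")["weight"].sum().reindex(months, fill_value=0.0)
    rate = num / denom.where(denom > 0)
    return rate


def private_share(records: pd.DataFrame, private_labels) -> pd.Series:
    """Weighted share of visits occurring in the private sector, per month.

    ``private_labels`` is the configured set of sector labels counted as
    private (e.g. private clinics/hospitals/pharmacies).  Months with zero
    visits are NaN (undefined), never zero.
    """
    private_labels = frozenset(private_labels)
    months = pd.Index(range(1, 13), name="month")
    visits = records.loc[records["visited"].astype(bool)]
    denom = visits.groupby("month")["weight"].sum().reindex(months, fill_value=0.0)
    num = (
        visits.loc[visits["sector"].isin(private_labels)]
        .groupby("month")["weight"]
        .sum()
        .reindex(months, fill_value=0.0)
    )
    return num / denom.where(denom > 0)


def relative_use(current: pd.Series, reference: pd.Series) -> pd.Series:
    """Current minus reference monthly rates, in percentage points.

    Nets out seasonal patterns by differencing against the most recent
    pre-pandemic survey year.  Missing months propagate as NaN.
    """
    cur = pd.Series(np.asarray(current, dtype=float), index=range(1, len(current) + 1))
    ref = pd.Series(np.asarray(reference, dtype=float), index=range(1, len(reference) + 1))
    if len(cur) != len(ref):
        raise DataError("current and reference series must have equal length")
    return (cur - ref) * 100.0
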