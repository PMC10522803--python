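"""Synthetic survey and time-series generators with known ground truth.

Real analyses of catastrophic health expenditure (CHE) rest on national
household-budget surveys (e.g. Mexico's ENIGH, Peru's ENAHO) that cannot be
redistributed.  This module emulates the statistical features the downstream
estimators depend on — zero-inflated right-skewed out-of-pocket (OOP)
spending, right-skewed consumption, positive expansion weights, an annual
CHE proportion with AR(1) dynamics plus an optional final-year shock, and
monthly utilisation series with seasonality and an intervention — while
keeping every ground-truth parameter available to the caller, so each
downstream stage can be tested without any external download.

All generators are deterministic given (config, seed) and return both the
generated table(s) and a ground-truth mapping recomputed by direct
enumeration over the emitted rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError

#: Column schema for generated household tables (one row per household).
HOUSEHOLD_COLUMNS = [
    "household_id",
    "weight",
    "consumption",
    "consumption_recall_days",
    "oop",
    "oop_recall_days",
    "insured",
    "n_members",
]

#: Column schema for generated person-month visit tables.
VISIT_COLUMNS = [
    "person_id",
    "weight",
    "year",
    "month",
    "visited",
    "sector",
    "country_convention",
]

_EPS = 1e-9


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(name, f"probability must lie in [0, 1], got {value}")


def _check_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ConfigError(name, f"must be strictly positive, got {value}")


@dataclass(frozen=True)
class SurveySimConfig:
    """Parameters of a single synthetic household-budget survey.

    Consumption is lognormal (``consumption_location`` / ``consumption_scale``
    on the log scale, currency units per year).  OOP spending is a
    zero-inflated Beta share of consumption: with probability
    ``oop_zero_prob`` a household spends nothing on health; otherwise its
    OOP-to-consumption ratio is Beta(``oop_share_alpha``,
    ``oop_share_beta``) on (0, 1), which guarantees OOP < consumption.
    Expansion weights are Gamma with coefficient of variation ``weight_cv``,
    mean-normalised to 1 and multiplied by ``expansion_factor``.
    """

    n_households: int = 2000
    consumption_location: float = 9.2
    consumption_scale: float = 0.7
    oop_zero_prob: float = 0.35
    oop_share_alpha: float = 0.8
    oop_share_beta: float = 12.0
    insurance_prob: float = 0.7
    weight_cv: float = 0.5
    expansion_factor: float = 1000.0
    consumption_recall_days: int = 365
    oop_recall_days: int = 365
    seed: int = 0

    def validate(self) -> None:
        if self.n_households < 1:
            raise ConfigError("n_households", "need at least one household")
        _check_positive("consumption_scale", self.consumption_scale)
        _check_prob("oop_zero_prob", self.oop_zero_prob)
        _check_positive("oop_share_alpha", self.oop_share_alpha)
        _check_positive("oop_share_beta", self.oop_share_beta)
        _check_prob("insurance_prob", self.insurance_prob)
        if self.weight_cv < 0:
            raise ConfigError("weight_cv", "coefficient of variation must be >= 0")
        _check_positive("expansion_factor", self.expansion_factor)
        _check_positive("consumption_recall_days", self.consumption_recall_days)
        _check_positive("oop_recall_days", self.oop_recall_days)


def _draw_weights(rng: np.random.Generator, n: int, cv: float, expansion: float) -> np.ndarray:
    """Positive, right-skewed expansion weights, mean-normalised then expanded."""
    if cv == 0:
        raw = np.ones(n)
    else:
        shape = 1.0 / cv**2
        raw = rng.gamma(shape, scale=1.0 / shape, size=n)
        raw = np.maximum(raw, _EPS)
    return raw / raw.mean() * expansion


def _enumerate_truth(table: pd.DataFrame) -> dict[str, float]:
    """Brute-force weighted enumeration over rows; the generator's ground truth.

    Kept as an explicit per-row accumulation so it is independent of the
    vectorised estimators in :mod:`chetrack.metrics`.
    """
    tot_w = che10 = che25 = ins = oop_sum = cons_sum = 0.0
    for row in table.itertuples(index=False):
        w = row.weight
        cons_annual = row.consumption * 365.0 / row.consumption_recall_days
        oop_annual = row.oop * 365.0 / row.oop_recall_days
        ratio = oop_annual / cons_annual
        tot_w += w
        if ratio > 0.10:
            che10 += w
        if ratio > 0.25:
            che25 += w
        if row.insured:
            ins += w
        oop_sum += w * oop_annual
        cons_sum += w * cons_annual
    return {
        "che10": che10 / tot_w,
        "che25": che25 / tot_w,
        "insurance": ins / tot_w,
        "oop_mean": oop_sum / tot_w,
        "consumption_mean": cons_sum / tot_w,
    }


def generate_household_survey(config: SurveySimConfig) -> tuple[pd.DataFrame, dict[str, float]]:
    """Generate one household survey table plus its realised ground truth.

    Returns
    -------
    table : pandas.DataFrame
        One row per household with columns :data:`HOUSEHOLD_COLUMNS`.
        Monetary amounts are expressed on their recall period (annual value
        scaled by ``recall_days / 365``), exactly as a survey would report
        them; downstream estimation must rescale to a common period.
    truth : dict
        Realised weighted population quantities (``che10``, ``che25``,
        ``insurance``, ``oop_mean``, ``consumption_mean``) computed by
        direct enumeration over the emitted rows; expenditure means are on
        the annual scale.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_households

    weight = _draw_weights(rng, n, config.weight_cv, config.expansion_factor)
    consumption_annual = rng.lognormal(
        mean=config.consumption_location, sigma=config.consumption_scale, size=n
    )
    zero = rng.random(n) < config.oop_zero_prob
    share = rng.beta(config.oop_share_alpha, config.oop_share_beta, size=n)
    # Keep strictly inside (0, 1) so OOP < consumption holds exactly.
    share = np.clip(share, _EPS, 1.0 - _EPS)
    share[zero] = 0.0
    oop_annual = share * consumption_annual
    insured = rng.random(n) < config.insurance_prob
    n_members = 1 + rng.poisson(2.5, size=n)

    table = pd.DataFrame(
        {
            "household_id": np.arange(n),
            "weight": weight,
            "consumption": consumption_annual * config.consumption_recall_days / 365.0,
            "consumption_recall_days": config.consumption_recall_days,
            "oop": oop_annual * config.oop_recall_days / 365.0,
            "oop_recall_days": config.oop_recall_days,
            "insured": insured,
            "n_members": n_members,
        }
    )
    return table, _enumerate_truth(table)


@dataclass(frozen=True)
class CheSeriesSimConfig:
    """Parameters of an annual national CHE series with AR(1) dynamics.

    The true CHE proportion follows ``p_t = ar_intercept + ar_slope * p_{t-1}
    + e_t`` with ``e_t ~ N(0, innovation_sd^2)``, started at the stationary
    mean ``ar_intercept / (1 - ar_slope)``.  ``shock_2020`` is added to the
    final year after the AR step, emulating a pandemic-year disturbance.
    The path is clamped to (0, 1) after shocks.
    """

    years: tuple[int, ...] = tuple(range(2004, 2021))
    ar_intercept: float = 0.02
    ar_slope: float = 0.8
    innovation_sd: float = 0.004
    shock_2020: float = 0.0
    households_per_year: int = 2000
    weight_cv: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if len(self.years) < 6:
            raise ConfigError("years", "need at least six survey years")
        if list(self.years) != sorted(set(self.years)):
            raise ConfigError("years", "years must be strictly increasing")
        if abs(self.ar_slope) >= 1.0:
            raise ConfigError("ar_slope", "|ar_slope| must be < 1 (stationarity)")
        mean = self.ar_intercept / (1.0 - self.ar_slope)
        if not (0.0 < mean < 1.0):
            raise ConfigError(
                "ar_intercept", f"implied stationary mean {mean:.4f} outside (0, 1)"
            )
        if self.innovation_sd < 0:
            raise ConfigError("innovation_sd", "must be >= 0")
        if self.households_per_year < 2:
            raise ConfigError("households_per_year", "need at least two households")
        if self.weight_cv < 0:
            raise ConfigError("weight_cv", "must be >= 0")


@dataclass
class AnnualSeriesSim:
    """A simulated annual CHE series: estimates, truth, and microdata."""

    series: pd.DataFrame  # columns: country, year, metric, value, se, n
    true_path: np.ndarray
    tables: dict[int, pd.DataFrame]
    config: CheSeriesSimConfig


def _true_che_path(config: CheSeriesSimConfig, rng: np.random.Generator) -> np.ndarray:
    mean = config.ar_intercept / (1.0 - config.ar_slope)
    path = np.empty(len(config.years))
    prev = mean
    for i in range(len(path)):
        prev = config.ar_intercept + config.ar_slope * prev
        if config.innovation_sd > 0:
            prev += rng.normal(0.0, config.innovation_sd)
        path[i] = prev
    path[-1] += config.shock_2020
    return np.clip(path, _EPS, 1.0 - _EPS)


def _kish_neff(weights: np.ndarray) -> float:
    return float(weights.sum() ** 2 / np.sum(weights**2))


def generate_che_annual_series(
    config: CheSeriesSimConfig, microdata: bool = True
) -> AnnualSeriesSim:
    """Simulate an annual CHE series around a known AR(1) truth.

    With ``microdata=True`` (default) each year gets a household table whose
    rows incur CHE independently with the year's true probability, so the
    weighted CHE estimate is unbiased for the path value; the emitted series
    holds the weighted estimates with Kish effective-sample-size standard
    errors.  With ``microdata=False`` the per-year estimate is drawn directly
    as truth plus normal noise at the analytic design-adjusted standard
    error — the sampling distribution the microdata route approximates —
    which keeps large replicate studies cheap.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _true_che_path(config, rng)

    rows = []
    tables: dict[int, pd.DataFrame] = {}
    deff = 1.0 + config.weight_cv**2  # Kish design effect for random weights
    for year, p in zip(config.years, truth):
        n = config.households_per_year
        if microdata:
            table = _household_table_with_che_prob(rng, n, p, config.weight_cv)
            tables[year] = table
            w = table["weight"].to_numpy()
            flags = (
                table["oop"].to_numpy() / table["consumption"].to_numpy() > 0.10
            ).astype(float)
            est = float(np.sum(w * flags) / w.sum())
            neff = _kish_neff(w)
        else:
            neff = n / deff
            est = float(np.clip(p + rng.normal(0.0, math.sqrt(p * (1 - p) / neff)), _EPS, 1 - _EPS))
        se = math.sqrt(max(est * (1.0 - est), _EPS) / neff)
        rows.append(
            {"country": "synthetic", "year": year, "metric": "che10",
             "value": est, "se": se, "n": neff}
        )
    series = pd.DataFrame(rows)
    return AnnualSeriesSim(series=series, true_path=truth, tables=tables, config=config)


def _household_table_with_che_prob(
    rng: np.random.Generator, n: int, p: float, weight_cv: float
) -> pd.DataFrame:
    """Household table whose weighted CHE(10%) estimate is unbiased for ``p``.

    CHE status is Bernoulli(p) per household; OOP shares are then drawn above
    or below the 10% threshold accordingly (flagged households may also
    exceed 25%, so the 25% rate is a proper subset).
    """
    flag = rng.random(n) < p
    share = np.where(flag, rng.uniform(0.105, 0.45, size=n), rng.uniform(0.0, 0.095, size=n))
    share[~flag & (rng.random(n) < 0.3)] = 0.0  # zero-inflation among non-CHE rows
    consumption = rng.lognormal(9.2, 0.7, size=n)
    weight = _draw_weights(rng, n, weight_cv, 1000.0)
    return pd.DataFrame(
        {
            "household_id": np.arange(n),
            "weight": weight,
            "consumption": consumption,
            "consumption_recall_days": 365,
            "oop": share * consumption,
            "oop_recall_days": 365,
            "insured": rng.random(n) < 0.7,
            "n_members": 1 + rng.poisson(2.5, size=n),
        }
    )


@dataclass(frozen=True)
class MonthlySimConfig:
    """Parameters of a monthly utilisation (or share) series with an intervention.

    The counterfactual series is ``baseline_rate + seasonal_amplitude *
    sin(2*pi*(t-1)/12)``.  From ``intervention_month`` (1-based) onward an
    additive ``level_shift`` applies, plus ``slope_shift`` per month elapsed
    since the intervention (zero at the intervention month itself).  All
    rate parameters and shifts are on the proportion scale; i.i.d. normal
    noise with sd ``noise_sd`` is added before clamping to [0, 1].
    """

    n_months: int = 24
    baseline_rate: float = 0.45
    seasonal_amplitude: float = 0.03
    level_shift: float = -0.2
    slope_shift: float = 0.0
    intervention_month: int = 16
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_months < 4:
            raise ConfigError("n_months", "need at least four months")
        _check_prob("baseline_rate", self.baseline_rate)
        if not (0.0 <= self.seasonal_amplitude <= max(self.baseline_rate, _EPS)):
            raise ConfigError(
                "seasonal_amplitude", "must lie in [0, baseline_rate]"
            )
        if not (1 <= self.intervention_month <= self.n_months):
            raise ConfigError("intervention_month", "must fall inside the series")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd", "must be >= 0")


@dataclass
class MonthlyUseSim:
    """A simulated monthly series with its noise-free counterfactual."""

    values: np.ndarray
    counterfactual: np.ndarray  # seasonal baseline, no intervention, no noise
    level_shift: float
    slope_shift: float
    intervention_month: int


def generate_monthly_use(config: MonthlySimConfig) -> MonthlyUseSim:
    """Simulate a monthly visit-rate series around a known intervention effect."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    t = np.arange(1, config.n_months + 1)
    counterfactual = config.baseline_rate + config.seasonal_amplitude * np.sin(
        2.0 * np.pi * (t - 1) / 12.0
    )
    post = t >= config.intervention_month
    effect = post * (config.level_shift + config.slope_shift * (t - config.intervention_month))
    values = counterfactual + effect
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=config.n_months)
    values = np.clip(values, 0.0, 1.0)
    return MonthlyUseSim(
        values=values,
        counterfactual=counterfactual,
        level_shift=config.level_shift,
        slope_shift=config.slope_shift,
        intervention_month=config.intervention_month,
    )


def generate_visit_records(
    month_visit_probs: np.ndarray,
    month_private_probs: np.ndarray,
    n_persons: int,
    year: int,
    convention: str = "monthly_recall",
    weight_cv: float = 0.5,
    seed: int = 0,
    private_label: str = "private_clinic",
    public_label: str = "public_hospital",
) -> pd.DataFrame:
    """Person-month visit microdata with known per-month visit and sector probabilities.

    One row per person per month; under ``annual_recall`` every respondent
    appears in all twelve months (the denominator is the whole sample, as
    when visits over the past year are recalled); under ``monthly_recall``
    each month's rows are an independent cross-section.
    """
    if convention not in ("annual_recall", "monthly_recall"):
        raise ConfigError("convention", f"unknown convention {convention!r}")
    month_visit_probs = np.asarray(month_visit_probs, dtype=float)
    month_private_probs = np.asarray(month_private_probs, dtype=float)
    if month_visit_probs.shape != (12,) or month_private_probs.shape != (12,):
        raise ConfigError("month_probs", "need exactly 12 monthly probabilities")
    rng = np.random.default_rng(seed)
    frames = []
    weights = _draw_weights(rng, n_persons, weight_cv, 100.0)
    for m in range(12):
        if convention == "monthly_recall":
            w = _draw_weights(rng, n_persons, weight_cv, 100.0)
            pid = np.arange(n_persons) + m * n_persons
        else:
            w = weights
            pid = np.arange(n_persons)
        visited = rng.random(n_persons) < month_visit_probs[m]
        private = rng.random(n_persons) < month_private_probs[m]
        sector = np.where(visited & private, private_label,
                          np.where(visited, public_label, "none"))
        frames.append(
            pd.DataFrame(
                {
                    "person_id": pid,
                    "weight": w,
                    "year": year,
                    "month": m + 1,
                    "visited": visited,
                    "sector": sector,
                    "country_convention": convention,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def config_echo(config) -> dict:
    """Plain-dict echo of a simulation config, for sidecar ground-truth files."""
    d = asdict(config)
    d["__type__"] = type(config).__name__
    return d
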