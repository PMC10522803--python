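"""End-to-end orchestration: simulate → metrics → forecast → ITS → report.

A single :func:`run_pipeline` call reproduces the whole study design on
synthetic data with known ground truth: it simulates an annual CHE history
with a configurable pandemic-year shock, re-estimates the series from the
household microdata with the survey-weighted estimators, forecasts the
final year from the earlier years with the autoregressive ensemble,
applies the UI-non-overlap rule, simulates monthly visit microdata around
a stay-at-home intervention, and runs the interrupted time-series
regressions on relative use and private-sector share.  Everything is
deterministic given (config, seed) and every table is written as CSV
together with a YAML run log (config echo, warnings, versions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ChetrackError
from .forecast import EnsembleForecast, OverlapVerdict, compare_intervals, forecast_series
from .its import ITSResult, fit_its
from .io import write_monthly_csv, write_series_csv, write_yaml
from .metrics import (
    PRIVATE_LABELS,
    household_metrics,
    monthly_visit_rate,
    private_share,
    relative_use,
    series_to_frame,
)
from .synthetic import (
    CheSeriesSimConfig,
    generate_che_annual_series,
    generate_visit_records,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Study-level constants and simulation settings for one pipeline run.

    Defaults mirror the study conventions: CHE thresholds 10%/25%, 1000
    uncertainty draws, stay-at-home orders taking effect from April 2020
    (the first full month after mid/late-March orders), Newey-West lag 1.
    """

    country: str = "synthetic"
    years: tuple[int, ...] = tuple(range(2004, 2021))
    che_thresholds: tuple[float, ...] = (0.10, 0.25)
    shock_2020: float = 0.05
    households_per_year: int = 1500
    n_draws: int = 1000
    holdout_years: int | None = None
    weighting: str = "equal"
    ppp_factor: float = 1.0
    nw_lag: int = 1
    convention: str = "monthly_recall"
    private_labels: tuple[str, ...] = tuple(sorted(PRIVATE_LABELS["peru"]))
    # Monthly utilisation ground truth (proportion scale)
    visit_baseline: float = 0.45
    visit_seasonal_amplitude: float = 0.03
    visit_level_shift: float = -0.20
    visit_slope_shift: float = 0.01
    private_share_base: float = 0.35
    private_share_shift: float = 0.20
    n_persons_per_month: int = 1500
    intervention_calendar_month: int = 4  # April: first full post-order month
    reference_year: int = 2019
    seed: int = 0

    def validate(self) -> None:
        from .errors import ConfigError

        for t in self.che_thresholds:
            if not (0.0 < t < 1.0):
                raise ConfigError("che_thresholds", f"threshold {t} outside (0, 1)")
        if self.n_draws < 100:
            raise ConfigError("n_draws", "need at least 100 draws")
        if not (1 <= self.intervention_calendar_month <= 12):
            raise ConfigError("intervention_calendar_month", "must be in 1..12")


@dataclass
class PipelineResult:
    series: pd.DataFrame
    forecast: EnsembleForecast
    verdict: OverlapVerdict
    observed_2020: tuple[float, float, float]  # value, se, n_eff
    true_2020: float
    its_visits: ITSResult
    its_private: ITSResult
    relative_visits: pd.Series
    private_pooled: pd.Series
    warnings_count: int


class _CountingHandler(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record):
        self.count += 1


def _month_probs(base, amp):
    m = np.arange(12)
    return np.clip(base + amp * np.sin(2 * np.pi * m / 12.0), 0.0, 1.0)


def _shifted_probs(base, amp, level, slope, start_month):
    p = _month_probs(base, amp)
    m = np.arange(1, 13)
    post = m >= start_month
    return np.clip(p + post * (level + slope * (m - start_month)), 0.0, 1.0)


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Run the full synthetic study; optionally write all outputs to ``outdir``."""
    config.validate()
    counter = _CountingHandler()
    logging.getLogger("chetrack").addHandler(counter)
    try:
        result = _run(config, outdir)
    except ChetrackError as exc:
        raise type(exc)(f"pipeline aborted: {exc}") from exc
    finally:
        logging.getLogger("chetrack").removeHandler(counter)
    result.warnings_count = counter.count
    if outdir is not None:
        _write_report(config, result, Path(outdir))
    return result


def _run(config: PipelineConfig, outdir) -> PipelineResult:
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=8)

    # 1. Simulate the annual CHE history (microdata per year).
    sim = generate_che_annual_series(
        CheSeriesSimConfig(
            years=config.years,
            shock_2020=config.shock_2020,
            households_per_year=config.households_per_year,
            seed=int(seeds[0]),
        )
    )

    # 2. Re-estimate every metric from the microdata with the survey estimators.
    points = []
    for year, table in sim.tables.items():
        points.extend(
            household_metrics(table, thresholds=config.che_thresholds,
                              ppp_factor=config.ppp_factor,
                              country=config.country, year=year)
        )
    series = series_to_frame(points).sort_values(["metric", "year"]).reset_index(drop=True)

    # 3. Forecast 2020 CHE from the pre-2020 estimates; UI-non-overlap verdict.
    che = series[series["metric"] == "che10"]
    history = che[che["year"] < config.years[-1]]
    observed = che[che["year"] == config.years[-1]].iloc[0]
    forecast = forecast_series(
        history["value"].to_numpy(), history["se"].to_numpy(),
        history["year"].tolist(),
        n_draws=config.n_draws, seed=int(seeds[1]),
        weighting=config.weighting, holdout_years=config.holdout_years,
    )
    obs_interval = (observed["value"] - 1.96 * observed["se"],
                    observed["value"] + 1.96 * observed["se"])
    verdict = compare_intervals(obs_interval, forecast.interval)

    # 4. Monthly utilisation: reference year vs intervention year.
    ref_visit_probs = _month_probs(config.visit_baseline,
                                   config.visit_seasonal_amplitude)
    cur_visit_probs = _shifted_probs(
        config.visit_baseline, config.visit_seasonal_amplitude,
        config.visit_level_shift, config.visit_slope_shift,
        config.intervention_calendar_month,
    )
    ref_private = np.full(12, config.private_share_base)
    cur_private = np.clip(
        config.private_share_base
        + (np.arange(1, 13) >= config.intervention_calendar_month)
        * config.private_share_shift,
        0.0, 1.0,
    )
    ref_records = generate_visit_records(
        ref_visit_probs, ref_private, config.n_persons_per_month,
        year=config.reference_year, convention=config.convention,
        seed=int(seeds[2]),
    )
    cur_records = generate_visit_records(
        cur_visit_probs, cur_private, config.n_persons_per_month,
        year=config.years[-1], convention=config.convention,
        seed=int(seeds[3]),
    )

    ref_rate = monthly_visit_rate(ref_records, config.convention)
    cur_rate = monthly_visit_rate(cur_records, config.convention)
    rel = relative_use(cur_rate, ref_rate)
    its_visits = fit_its(rel.to_numpy(),
                         intervention_position=config.intervention_calendar_month,
                         lag=config.nw_lag)

    # Private share is pooled across both years (no seasonal netting) with a
    # year intercept for the later year, as in a biennial-survey design.
    labels = frozenset(config.private_labels)
    ref_share = private_share(ref_records, labels)
    cur_share = private_share(cur_records, labels)
    pooled = pd.concat([ref_share, cur_share], ignore_index=True)
    pooled.index = range(1, 25)
    year_labels = [config.reference_year] * 12 + [config.years[-1]] * 12
    its_private = fit_its(
        pooled.to_numpy(),
        intervention_position=12 + config.intervention_calendar_month,
        lag=config.nw_lag,
        year_labels=year_labels,
        dummy_years=[config.years[-1]],
    )

    return PipelineResult(
        series=series,
        forecast=forecast,
        verdict=verdict,
        observed_2020=(float(observed["value"]), float(observed["se"]),
                       float(observed["n"])),
        true_2020=float(sim.true_path[-1]),
        its_visits=its_visits,
        its_private=its_private,
        relative_visits=rel,
        private_pooled=pooled,
        warnings_count=0,
    )


def _its_frame(result: ITSResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "coefficient": result.params.index,
            "estimate": result.params.to_numpy(),
            "nw_se": result.nw_se.to_numpy(),
            "ci_lower": result.ci95["lower"].to_numpy(),
            "ci_upper": result.ci95["upper"].to_numpy(),
            "lag": result.lag_used,
            "n_obs": result.n_obs,
        }
    )


def _write_report(config: PipelineConfig, result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_series_csv(result.series, outdir / "series.csv")

    fc = result.forecast
    pd.DataFrame(
        [
            {
                "country": config.country,
                "target_year": fc.target_year,
                "predicted_mean": fc.mean,
                "predicted_lower": fc.lower,
                "predicted_upper": fc.upper,
                "observed_value": result.observed_2020[0],
                "observed_lower": result.verdict.observed_interval[0],
                "observed_upper": result.verdict.observed_interval[1],
                "different": result.verdict.different,
                **{f"rmse_{k}": v for k, v in fc.per_model_rmse.items()},
            }
        ]
    ).to_csv(outdir / "forecast.csv", index=False)

    _its_frame(result.its_visits).to_csv(outdir / "its_visits.csv", index=False)
    _its_frame(result.its_private).to_csv(outdir / "its_private_share.csv", index=False)

    monthly = pd.DataFrame(
        {
            "year": config.years[-1],
            "month": result.relative_visits.index,
            "outcome": result.relative_visits.to_numpy(),
            "respondents": config.n_persons_per_month,
        }
    )
    write_monthly_csv(monthly, outdir / "relative_visits.csv")

    write_yaml(
        {
            "config": asdict(config),
            "package_version": __version__,
            "seed": config.seed,
            "warnings": result.warnings_count,
            "verdict_different": bool(result.verdict.different),
            "true_2020_che": result.true_2020,
        },
        outdir / "run_log.yaml",
    )
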