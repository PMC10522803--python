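"""Autoregressive ensemble counterfactual for short annual series.

For each country and metric the expected 2020 value "had past trends
continued" is forecast from the 2004–19 history alone, using the four
latent-trend autoregressive forms: the level regressed on its lag and the
first difference regressed on its lagged difference, each with and without
a constant.  Models are compared by rolling-origin out-of-sample RMSE and
combined in an ensemble; prediction uncertainty mixes draws from each
model's coefficient sampling distribution with draws of the observed series
perturbed by its per-point sampling standard errors, summarised as the
mean and the 2.5th/97.5th percentiles (the 95% uncertainty interval, UI).
An observed value is declared *different* from its counterfactual when the
observed and predicted UIs do not overlap.

Series are short (6–17 points), so models with multiple lags or moving
averages are deliberately out of scope.  Calendar gaps (e.g. a series
observed in 2004 then 2010–14) are treated as consecutive observations in
the lag structure, with a logged warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import DegenerateFitError, EnsembleError, FitError

logger = logging.getLogger(__name__)

_MIN_PAIRS = 4  # minimum usable (lag, value) pairs for a fit


class ARForm(str, Enum):
    LEVEL = "level_on_lag_level"
    DIFF = "diff_on_lag_diff"


@dataclass(frozen=True)
class ARModelSpec:
    """One of the four admissible autoregressive forms."""

    form: ARForm
    include_constant: bool

    @property
    def name(self) -> str:
        const = "const" if self.include_constant else "noconst"
        return f"{self.form.value}_{const}"


#: The four admissible model specifications (2 forms × 2 constant options).
ALL_SPECS: tuple[ARModelSpec, ...] = tuple(
    ARModelSpec(form, c) for form in (ARForm.LEVEL, ARForm.DIFF) for c in (True, False)
)


@dataclass
class FittedAR:
    spec: ARModelSpec
    intercept: float  # 0 when the constant is excluded
    slope: float
    residual_sd: float
    coef_cov: np.ndarray  # 2x2 (const, slope) or 1x1 (slope only)
    n_obs: int


def _lag_pairs(values: np.ndarray, spec: ARModelSpec) -> tuple[np.ndarray, np.ndarray]:
    if spec.form is ARForm.LEVEL:
        return values[:-1], values[1:]
    d = np.diff(values)
    return d[:-1], d[1:]


def fit_ar(values, spec: ARModelSpec) -> FittedAR:
    """OLS fit of one autoregressive form to an ordered series.

    Observations are assumed chronologically ordered; any calendar gaps are
    treated as consecutive steps (warned about by the caller).  Coefficient
    covariance is the classical OLS ``s² (X'X)⁻¹``.
    """
    values = np.asarray(values, dtype=float)
    x, y = _lag_pairs(values, spec)
    n = len(y)
    if n < _MIN_PAIRS:
        raise FitError(
            f"{spec.name}: need at least {_MIN_PAIRS} usable lag pairs, have {n}"
        )
    X = np.column_stack([np.ones(n), x]) if spec.include_constant else x[:, None]
    k = X.shape[1]
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    if rank < k:
        # Zero-variance regressor: acceptable only when the minimum-norm
        # solution is exact (e.g. a constant series), with no sampling
        # uncertainty attached; otherwise the fit is genuinely degenerate.
        scale = max(1.0, float(np.abs(y).max(initial=0.0)))
        if not np.allclose(resid, 0.0, atol=1e-10 * scale):
            raise DegenerateFitError(f"{spec.name}: zero-variance regressor")
        cov = np.zeros((k, k))
        sigma = 0.0
    else:
        dof = n - k
        sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
        cov = sigma2 * np.linalg.inv(X.T @ X)
        sigma = np.sqrt(sigma2)
    if spec.include_constant:
        intercept, slope = float(beta[0]), float(beta[1])
    else:
        intercept, slope = 0.0, float(beta[0])
    return FittedAR(spec, intercept, slope, float(sigma), cov, n)


def _predict_from_coefs(spec: ARModelSpec, intercept: float, slope, last_value, last_diff):
    if spec.form is ARForm.LEVEL:
        return intercept + slope * last_value
    return last_value + intercept + slope * last_diff


def predict_next(model: FittedAR, values) -> float:
    """One-step-ahead point prediction for the period after the last observed."""
    values = np.asarray(values, dtype=float)
    last = values[-1]
    last_diff = values[-1] - values[-2] if len(values) >= 2 else 0.0
    return float(
        _predict_from_coefs(model.spec, model.intercept, model.slope, last, last_diff)
    )


def oos_rmse(values, spec: ARModelSpec, holdout_years: int) -> float:
    """Rolling-origin one-step-ahead out-of-sample RMSE over the last points.

    For each of the last ``holdout_years`` observations, the model is
    refitted on strictly earlier data and its one-step prediction error
    recorded; the root mean squared error is returned.
    """
    values = np.asarray(values, dtype=float)
    if holdout_years < 1:
        raise FitError("holdout_years must be >= 1")
    n = len(values)
    min_fit = _MIN_PAIRS + (1 if spec.form is ARForm.LEVEL else 2)
    if n - holdout_years < min_fit:
        raise FitError(
            f"{spec.name}: holdout of {holdout_years} leaves only "
            f"{n - holdout_years} points to fit (need {min_fit})"
        )
    errors = []
    for i in range(n - holdout_years, n):
        model = fit_ar(values[:i], spec)
        errors.append(predict_next(model, values[:i]) - values[i])
    return float(np.sqrt(np.mean(np.square(errors))))


def default_holdout(n_obs: int) -> int:
    """Default rolling-origin depth for short series: min(3, n_obs - 6)."""
    return max(1, min(3, n_obs - 6))


@dataclass
class EnsembleForecast:
    """Counterfactual prediction for the year after the series ends."""

    target_year: int
    draws: np.ndarray
    mean: float
    lower: float  # 2.5th percentile of draws
    upper: float  # 97.5th percentile of draws
    per_model_rmse: dict[str, float]
    specs_used: tuple[ARModelSpec, ...]
    n_clamped: int = 0

    @property
    def interval(self) -> tuple[float, float]:
        return (self.lower, self.upper)


@dataclass(frozen=True)
class OverlapVerdict:
    """Decision from the UI-non-overlap rule."""

    observed_interval: tuple[float, float]
    predicted_interval: tuple[float, float]
    different: bool


def compare_intervals(observed, predicted) -> OverlapVerdict:
    """Declare the observed value different iff the two UIs are disjoint.

    Intervals are closed: touching endpoints overlap, hence "not different".
    """
    olo, ohi = float(observed[0]), float(observed[1])
    plo, phi = float(predicted[0]), float(predicted[1])
    if olo > ohi or plo > phi:
        raise ValueError("interval bounds must be ordered (lower, upper)")
    different = olo > phi or plo > ohi
    return OverlapVerdict((olo, ohi), (plo, phi), different)


def _sample_coefs(rng: np.random.Generator, model: FittedAR, size: int) -> np.ndarray:
    """Draw (intercept, slope) pairs from the normal coefficient approximation."""
    if model.spec.include_constant:
        mean = np.array([model.intercept, model.slope])
        draws = rng.multivariate_normal(mean, model.coef_cov, size=size,
                                        method="svd")
        return draws
    sd = np.sqrt(model.coef_cov[0, 0])
    slopes = rng.normal(model.slope, sd, size=size)
    return np.column_stack([np.zeros(size), slopes])


def ensemble_predict(
    values,
    ses,
    target_year: int,
    n_draws: int = 1000,
    seed: int = 0,
    weighting: str = "equal",
    clamp: tuple[float, float] | None = (0.0, 1.0),
    include_innovation: bool = False,
    crossed: bool = False,
    holdout_years: int | None = None,
) -> EnsembleForecast:
    """Ensemble counterfactual with model- and data-uncertainty draws.

    Each retained draw pairs one coefficient draw (sampled from a fitted
    model's OLS coefficient distribution) with one data draw (the observed
    series perturbed by per-point normal noise at its standard errors,
    clamped to natural limits).  Draws are allocated across the admissible
    model specs either equally (default) or proportionally to inverse
    out-of-sample RMSE (``weighting="inverse_rmse"``).  With
    ``crossed=True`` every coefficient draw is applied to every data draw
    (``n_draws²`` retained draws).  ``include_innovation`` adds the fitted
    residual innovation to each draw; by default the UI describes the
    predicted mean level only.

    Unfittable specs are dropped with a warning; if none fit, an
    :class:`EnsembleError` is raised.
    """
    values = np.asarray(values, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if values.shape != ses.shape:
        raise ValueError("values and ses must have equal length")
    rng = np.random.default_rng(seed)

    fits: list[FittedAR] = []
    rmse: dict[str, float] = {}
    hold = default_holdout(len(values)) if holdout_years is None else holdout_years
    for spec in ALL_SPECS:
        try:
            fits.append(fit_ar(values, spec))
        except FitError as exc:
            logger.warning("dropping unfittable spec: %s", exc)
            continue
        try:
            rmse[spec.name] = oos_rmse(values, spec, hold)
        except FitError:
            rmse[spec.name] = float("nan")
    if not fits:
        raise EnsembleError("none of the four autoregressive specs could be fitted")

    # Data draws: perturb every observed point by its sampling SE.
    perturbed = values[None, :] + rng.normal(size=(n_draws, len(values))) * ses[None, :]
    if clamp is not None:
        perturbed = np.clip(perturbed, clamp[0], clamp[1])
    last = perturbed[:, -1]
    last_diff = perturbed[:, -1] - perturbed[:, -2]

    # Allocate draws across models.
    if weighting == "equal":
        w = np.ones(len(fits))
    elif weighting == "inverse_rmse":
        w = np.array([1.0 / rmse[f.spec.name] if rmse[f.spec.name] > 0 else 0.0
                      for f in fits])
        if not np.any(w > 0):
            w = np.ones(len(fits))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    w = w / w.sum()
    counts = np.floor(w * n_draws).astype(int)
    counts[: n_draws - counts.sum()] += 1  # distribute the remainder

    draws = []
    offset = 0  # model-draw i is paired with data-draw i (not crossed)
    for model, count in zip(fits, counts):
        if count == 0:
            continue
        coefs = _sample_coefs(rng, model, count)
        if crossed:
            pred = _predict_from_coefs(
                model.spec, coefs[:, 0][:, None], coefs[:, 1][:, None],
                last[None, :], last_diff[None, :],
            ).ravel()
        else:
            idx = np.arange(offset, offset + count)
            offset += count
            pred = _predict_from_coefs(
                model.spec, coefs[:, 0], coefs[:, 1], last[idx], last_diff[idx]
            )
        if include_innovation:
            pred = pred + rng.normal(0.0, model.residual_sd, size=pred.shape)
        draws.append(np.asarray(pred, dtype=float))
    draws = np.concatenate(draws)

    n_clamped = 0
    if clamp is not None:
        n_clamped = int(np.sum((draws < clamp[0]) | (draws > clamp[1])))
        if n_clamped:
            logger.warning("clamped %d of %d ensemble draws to %s",
                           n_clamped, draws.size, clamp)
        draws = np.clip(draws, clamp[0], clamp[1])

    return EnsembleForecast(
        target_year=target_year,
        draws=draws,
        mean=float(draws.mean()),
        lower=float(np.percentile(draws, 2.5)),
        upper=float(np.percentile(draws, 97.5)),
        per_model_rmse=rmse,
        specs_used=tuple(f.spec for f in fits),
        n_clamped=n_clamped,
    )


def forecast_series(series_values, series_ses, years, **kwargs) -> EnsembleForecast:
    """Convenience wrapper: forecast the year after the last in ``years``.

    Warns when the year sequence has calendar gaps, which the lag structure
    treats as consecutive steps.
    """
    years = list(years)
    if any(b - a != 1 for a, b in zip(years, years[1:])):
        logger.warning(
            "series has calendar gaps (%s); lag regressions treat observed "
            "points as consecutive", years,
        )
    return ensemble_predict(series_values, series_ses,
                            target_year=years[-1] + 1, **kwargs)
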