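"""CSV readers/writers for the documented table schemas.

Three tidy schemas move between pipeline stages (all plain CSV, versioned
in docs/methods.md):

* series:    country, year, metric, value, se, n          (aggregated points)
* household: household_id, weight, consumption, consumption_recall_days,
             oop, oop_recall_days, insured, n_members     (one row/household)
* monthly:   year, month, outcome, respondents            (one row/month)

Readers validate headers and values and raise :class:`ParseError` naming
the offending row; every writer round-trips through its own reader.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError
from .metrics import SeriesPoint
from .synthetic import HOUSEHOLD_COLUMNS

SERIES_COLUMNS = ["country", "year", "metric", "value", "se", "n"]
MONTHLY_COLUMNS = ["year", "month", "outcome", "respondents"]

VALID_METRICS = {
    "che10", "che25", "insurance", "oop_mean", "consumption_mean",
    "visits", "private_share",
}


def _read_checked(path, columns) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df[list(columns)]


def read_series_csv(path) -> pd.DataFrame:
    """Read and validate an aggregated series table, sorted by (metric, year)."""
    df = _read_checked(path, SERIES_COLUMNS)
    if df.empty:
        raise ParseError(f"{path}: series file has a header but no rows")
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if row["metric"] not in VALID_METRICS:
            raise ParseError(f"{path} line {line}: unknown metric {row['metric']!r}")
        for col in ("value", "se", "n"):
            if not np.isfinite(row[col]):
                raise ParseError(f"{path} line {line}: non-numeric {col}")
        if row["se"] < 0:
            raise ParseError(f"{path} line {line}: negative standard error")
    df = df.sort_values(["country", "metric", "year"], kind="stable")
    return df.reset_index(drop=True)


def write_series_csv(points, path) -> None:
    """Write SeriesPoints (or an equivalent DataFrame) as tidy CSV."""
    if isinstance(points, pd.DataFrame):
        df = points[SERIES_COLUMNS]
    else:
        df = pd.DataFrame([vars(p) for p in points], columns=SERIES_COLUMNS)
    df.to_csv(path, index=False)


def series_points(df: pd.DataFrame) -> list[SeriesPoint]:
    return [SeriesPoint(r.country, int(r.year), r.metric, float(r.value),
                        float(r.se), float(r.n))
            for r in df.itertuples(index=False)]


def read_household_csv(path) -> pd.DataFrame:
    """Read and validate a household microdata table."""
    df = _read_checked(path, HOUSEHOLD_COLUMNS)
    bad = df.index[(df["weight"] <= 0) | (df["consumption"] <= 0)
                   | (df["oop"] < 0) | (df["consumption_recall_days"] <= 0)
                   | (df["oop_recall_days"] <= 0)]
    if len(bad):
        raise ParseError(f"{path} line {bad[0] + 2}: household row violates "
                         "positivity constraints")
    df["insured"] = df["insured"].astype(bool)
    return df


def write_household_csv(table: pd.DataFrame, path) -> None:
    table[HOUSEHOLD_COLUMNS].to_csv(path, index=False)


def read_monthly_csv(path) -> pd.DataFrame:
    """Read and validate a monthly outcome table."""
    df = _read_checked(path, MONTHLY_COLUMNS)
    bad = df.index[(df["month"] < 1) | (df["month"] > 12)]
    if len(bad):
        raise ParseError(f"{path} line {bad[0] + 2}: month outside 1..12")
    return df


def write_monthly_csv(df: pd.DataFrame, path) -> None:
    df[MONTHLY_COLUMNS].to_csv(path, index=False)


def write_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
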