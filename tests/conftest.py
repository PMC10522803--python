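import numpy as np
import pandas as pd
import pytest


def random_household_table(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Ad-hoc household table with varied weights, recalls and spending."""
    consumption = rng.lognormal(9.0, 0.8, size=n)
    share = rng.beta(0.7, 8.0, size=n)
    share[rng.random(n) < 0.3] = 0.0
    cons_recall = rng.choice([30, 90, 365], size=n)
    oop_recall = rng.choice([14, 30, 365], size=n)
    return pd.DataFrame(
        {
            "household_id": np.arange(n),
            "weight": rng.gamma(4.0, 250.0, size=n) + 1e-6,
            "consumption": consumption * cons_recall / 365.0,
            "consumption_recall_days": cons_recall,
            "oop": share * consumption * oop_recall / 365.0,
            "oop_recall_days": oop_recall,
            "insured": rng.random(n) < 0.6,
            "n_members": 1 + rng.poisson(2.0, size=n),
        }
    )


def brute_force_weighted_share(table: pd.DataFrame, predicate) -> float:
    """Literal per-row weighted enumeration, independent of the estimators."""
    num = 0.0
    den = 0.0
    for _, row in table.iterrows():
        den += row["weight"]
        if predicate(row):
            num += row["weight"]
    return num / den


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
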