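import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from afcf.meta_table import CATEGORICAL, NUMERIC, SCORE, MetaTable, RhythmLabel

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_numeric_table(n: int, seed: int, n_noise: int = 9,
                       with_copy: bool = True,
                       prevalence: float = 0.3) -> MetaTable:
    """Binary-labeled table with an optional exact label-copy feature plus
    i.i.d. noise features."""
    rng = np.random.default_rng(seed)
    y = rng.random(n) < prevalence
    data = {}
    if with_copy:
        data["copy"] = y.astype(float)
    for j in range(n_noise):
        data[f"noise_{j}"] = rng.standard_normal(n)
    idx = pd.Index([f"r{i:05d}" for i in range(n)], name="record_id")
    labels = pd.Series(
        [RhythmLabel.AFIB if v else RhythmLabel.NON_AFIB for v in y], index=idx
    )
    return MetaTable(pd.DataFrame(data, index=idx),
                     {c: NUMERIC for c in data}, labels)


@pytest.fixture
def small_vote_table() -> MetaTable:
    """3 records, 1 categorical vote + 1 continuous score, labeled."""
    idx = pd.Index(["a", "b", "c"], name="record_id")
    data = pd.DataFrame(
        {
            "alg": [RhythmLabel.AFIB, RhythmLabel.NON_AFIB, RhythmLabel.NOISY],
            "score": [0.9, 0.1, 0.5],
        },
        index=idx,
    )
    labels = pd.Series(
        [RhythmLabel.AFIB, RhythmLabel.NON_AFIB, RhythmLabel.NOISY], index=idx
    )
    return MetaTable(data, {"alg": CATEGORICAL, "score": SCORE}, labels)
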