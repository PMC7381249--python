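import numpy as np
import pandas as pd
import pytest

from cd8mir.io_core import ExpressionMatrix, NoiseStats, SampleTable, ValueKind


@pytest.fixture
def small_intensity_matrix() -> ExpressionMatrix:
    df = pd.DataFrame(
        {"s1": [100.0, 79.0, 81.0], "s2": [120.0, 60.0, 95.0]},
        index=["f1", "f2", "f3"],
    )
    return ExpressionMatrix(df, ValueKind.RAW_INTENSITY)


@pytest.fixture
def simple_noise() -> NoiseStats:
    return NoiseStats(
        pd.DataFrame(
            {"noise_mean": [10.0, 10.0], "noise_sd": [5.0, 5.0]},
            index=pd.Index(["s1", "s2"], name="sample_id"),
        )
    )


@pytest.fixture
def seeded_log2_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(7)
    df = pd.DataFrame(
        rng.normal(8, 1, size=(60, 4)),
        index=[f"f{i}" for i in range(60)],
        columns=[f"s{i}" for i in range(4)],
    )
    return ExpressionMatrix(df, ValueKind.LOG2)


def make_meta(sample_ids, smokers, condition="control", pair_ids=None):
    n = len(sample_ids)
    df = pd.DataFrame(
        {
            "diagnosis": ["RA" if i % 2 == 0 else "HC" for i in range(n)],
            "smoker": [s in set(smokers) for s in sample_ids],
            "condition": condition if isinstance(condition, str) else list(condition),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if pair_ids is not None:
        df["pair_id"] = list(pair_ids)
    return SampleTable(df)
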