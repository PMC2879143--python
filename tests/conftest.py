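import numpy as np
import pandas as pd
import pytest

from protmap.quantify import CountMatrix


def build_counts(values: dict, conditions: list[str], stages: list[str] | None = None):
    """CountMatrix from {sample_id: per-protein values}; proteins auto-named."""
    df = pd.DataFrame(values, dtype=float)
    if df.index.dtype != object:
        df.index = [f"P{i:03d}" for i in range(1, len(df) + 1)]
    stages = stages or ["s1"] * len(df.columns)
    design = pd.DataFrame(
        {"condition": conditions, "stage": stages}, index=df.columns
    )
    return CountMatrix(values=df, design=design)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
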