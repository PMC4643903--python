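import numpy as np
import pandas as pd
import pytest

from resistwoc import Condition, ExperimentTable


@pytest.fixture
def two_round_table():
    """Tiny hand-built experiment: 4 subjects, 2 rounds, full information."""
    df = pd.DataFrame({
        "subject_id": ["a", "b", "c", "d"] * 2,
        "round": [1] * 4 + [2] * 4,
        "estimate": [1.0, 10.0, 100.0, 1000.0, 2.0, 12.0, 90.0, 500.0],
    })
    return ExperimentTable(data=df, condition=Condition.FULL, truth=50.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
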