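import numpy as np
import pandas as pd
import pytest

from promap import ConditionPair, ProteinProfile


@pytest.fixture
def four_channel_profile() -> ProteinProfile:
    """Small four-channel run with one missing cell."""
    frame = pd.DataFrame(
        {
            "114": [10.0, 40.0, 7.0],
            "115": [20.0, 60.0, np.nan],
            "116": [5.0, 30.0, 6.0],
            "117": [5.0, 20.0, 8.0],
        },
        index=pd.Index(["p1", "p2", "p3"], name="protein_id"),
    )
    return ProteinProfile(run_id="run1", intensities=frame)


@pytest.fixture
def small_pair() -> ConditionPair:
    rng = np.random.default_rng(42)
    n = 50
    values = rng.lognormal(mean=10, sigma=1.5, size=(n, 2))
    ids = np.array([f"p{i}" for i in range(n)], dtype=object)
    return ConditionPair(ids=ids, a=values[:, 0], b=values[:, 1])
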