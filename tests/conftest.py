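from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ercflow.preprocess import Channel, EpochSet
from ercflow.synthetic import default_session_network, simulate_session


def make_epochset(
    data: np.ndarray,
    window: tuple[float, float] = (-0.6, 0.4),
    sampling_rate: float = 1250.0,
    alignment: str = "speech_onset",
    conditions=None,
    regions=None,
) -> EpochSet:
    """Wrap a (trials, channels, samples) array in an EpochSet."""
    nt, K, _ = data.shape
    if conditions is None:
        conditions = ["word" if i % 2 == 0 else "pseudoword" for i in range(nt)]
    if regions is None:
        regions = ["STN"] * K
    trials = pd.DataFrame(
        {
            "trial_id": np.arange(nt),
            "condition": conditions,
            "kept": [True] * nt,
            "reject_reason": [""] * nt,
        }
    )
    return EpochSet(
        data=np.asarray(data, dtype=float),
        alignment=alignment,
        window=window,
        sampling_rate=sampling_rate,
        channels=tuple(Channel(f"ch{i}", regions[i]) for i in range(K)),
        trials=trials,
    )


@pytest.fixture(scope="session")
def default_sim():
    """One simulated default-motif session (60 trials, seed 1)."""
    return simulate_session(default_session_network(0), n_trials=60, seed=1)


@pytest.fixture(scope="session")
def default_session_result(default_sim):
    from ercflow.pipeline import run_session

    return run_session(default_sim)
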