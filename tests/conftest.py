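import numpy as np
import pandas as pd
import pytest

from timedecode import (
    AnalysisConfig,
    EpochedRecording,
    SyntheticConfig,
    make_pattern_bank,
    simulate_participant,
)


@pytest.fixture(scope="session")
def fast_cfg() -> AnalysisConfig:
    """Analysis config with cheap shuffle/permutation counts for unit tests."""
    return AnalysisConfig(n_shuffles=2, n_permutations=200)


@pytest.fixture(scope="session")
def small_synthetic():
    """One simulated participant, modest trial count, defaults otherwise."""
    syn = SyntheticConfig(n_trials_per_condition=32, rng_seed=7)
    bank = make_pattern_bank(syn.n_channels, 4, seed=11)
    return simulate_participant(syn, bank, "sim01", seed=13)


@pytest.fixture()
def toy_recording():
    """Tiny deterministic recording: 6 trials, 3 channels, 100 Hz."""
    times = np.arange(-500.0, 500.0, 10.0)
    rng = np.random.default_rng(0)
    data = rng.normal(size=(6, 3, len(times)))
    rec = EpochedRecording(
        data=data,
        times=times,
        srate=100.0,
        channel_labels=["A", "B", "C"],
        participant_id="p1",
    )
    table = pd.DataFrame(
        {
            "sf_value": np.linspace(1.0, 4.0, 6),
            "sf_class": 0,
            "color_index": 1,
            "availability": "short",
            "relevance": "sf",
            "correct": [True, True, False, True, True, True],
            "participant_id": "p1",
        }
    )
    return rec, table
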