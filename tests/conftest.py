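import numpy as np
import pandas as pd
import pytest

from admkit import (
    PopulationConfig,
    draw_population,
    select_block_sequence,
    sequences_to_frame,
    simulate_session,
)


@pytest.fixture(scope="session")
def small_blocks():
    """One 6-trial block with full-length (30-pair) sequences."""
    return [select_block_sequence(123, n_candidates=5, n_trials=6)]


@pytest.fixture(scope="session")
def small_sequences(small_blocks):
    return sequences_to_frame(small_blocks)


@pytest.fixture(scope="session")
def small_dataset(small_blocks, small_sequences):
    """Three synthetic subjects on the small block (both tasks)."""
    rng = np.random.default_rng(2024)
    subjects = draw_population(3, rng, PopulationConfig())
    traces = pd.concat(
        [simulate_session(s, small_blocks, rng) for s in subjects],
        ignore_index=True,
    )
    return traces, small_sequences, subjects


def toy_tables():
    """Two-pair toy: ie_rescaled (0.4, 0.0), final positions (0.2, 0.1)."""
    sequences = pd.DataFrame({
        "block": [1, 1], "trial": [1, 1], "pair": [1, 2],
        "ie_level": [0.4, 0.0], "ie_rescaled": [0.4, 0.0],
        "simple_ae": [0.4, 0.2],
    })
    traces = pd.DataFrame({
        "subject": ["s1"] * 2, "task": ["perceptual"] * 2,
        "block": [1, 1], "trial": [1, 1], "pair": [1, 2],
        "t_seconds": [1.0, 2.0], "y": [0.2, 0.1],
    })
    return traces, sequences
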