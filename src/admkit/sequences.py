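"""Random-walk stimulus sequences for the evidence-averaging task.

A trial presents 30 stimulus pairs in series.  The signed difference between
the right and left stimulus of the currently shown pair is the instantaneous
evidence (IE); its running mean is the (simple) average evidence (AE) that
subjects report with the slider.  IE lives on a nine-level alphabet
{-0.4, -0.3, ..., +0.4} and evolves as a bounded random walk so that the AE
changes smoothly within a trial.  Blocks of 15 trials are chosen from a pool
of candidates to minimise the pooled correlation between IE and AE, which
decorrelates the two quantities a reporter could be tracking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IE_LEVELS",
    "N_PAIRS",
    "N_TRIALS_PER_BLOCK",
    "EvidenceSequence",
    "BlockSequence",
    "generate_trial_sequence",
    "select_block_sequence",
    "generate_session_sequences",
    "rescale_ie_level",
    "sequences_to_frame",
    "as_rng",
]

#: The nine signed IE levels, in arbitrary units, spacing 0.1.
IE_LEVELS: np.ndarray = np.round(np.arange(-4, 5) / 10.0, 1)
IE_LEVELS.setflags(write=False)

N_PAIRS = 30
N_TRIALS_PER_BLOCK = 15
N_CANDIDATES = 100
WALK_RATE = 0.3

#: Rescaling of an IE level to the slider's -1..+1 scale.  One |level| step
#: of 0.1 moves 7% of the white squares from one grid to the other, i.e. a
#: 14-percentage-point between-grid difference; the slider endpoints mean a
#: 60% difference, so level x maps to x * 140 / 60.
IE_RESCALE_FACTOR = 140.0 / 60.0


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed, ``SeedSequence`` or ``Generator`` to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def rescale_ie_level(level):
    """Map IE alphabet values to the signed -1..+1 slider scale."""
    return np.asarray(level, dtype=float) * IE_RESCALE_FACTOR


@dataclass(frozen=True)
class EvidenceSequence:
    """One trial's IE series and its running simple average.

    Attributes
    ----------
    trial_index : int
        1-based trial index within the block.
    ie : ndarray
        Length-30 IE values on the nine-level alphabet.
    simple_ae : ndarray
        Running cumulative mean of ``ie`` (same, alphabet units).
    """

    trial_index: int
    ie: np.ndarray
    simple_ae: np.ndarray = field(default=None)

    def __post_init__(self):
        ie = np.asarray(self.ie, dtype=float)
        object.__setattr__(self, "ie", ie)
        if self.simple_ae is None:
            object.__setattr__(
                self, "simple_ae", np.cumsum(ie) / np.arange(1, ie.size + 1)
            )

    @property
    def ie_rescaled(self) -> np.ndarray:
        return rescale_ie_level(self.ie)


@dataclass(frozen=True)
class BlockSequence:
    """A block of 15 trial sequences with its pooled IE-AE correlation."""

    trials: tuple
    ie_ae_correlation: float

    def pooled(self):
        ie = np.concatenate([t.ie for t in self.trials])
        ae = np.concatenate([t.simple_ae for t in self.trials])
        return ie, ae


def generate_trial_sequence(rng_seed, walk_rate: float = WALK_RATE,
                            n_steps: int = N_PAIRS,
                            trial_index: int = 1) -> EvidenceSequence:
    """Simulate one trial's IE series as a bounded random walk.

    The initial level is drawn uniformly from the alphabet.  Each of the
    remaining steps moves up or down according to whether a Uniform(0,1)
    draw exceeds 0.5 (ties count as up), with magnitude
    ``(Poisson(walk_rate) + 1) / 10`` alphabet units; values that would
    leave [-0.4, +0.4] are clipped to the boundary.
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    if walk_rate < 0:
        raise ValueError(f"walk_rate must be >= 0, got {walk_rate}")
    rng = as_rng(rng_seed)
    # integer arithmetic on tenths keeps values exactly on the grid
    level = np.empty(n_steps, dtype=np.int64)
    level[0] = rng.integers(-4, 5)
    for s in range(1, n_steps):
        direction = 1 if rng.uniform() >= 0.5 else -1
        magnitude = rng.poisson(walk_rate) + 1
        level[s] = np.clip(level[s - 1] + direction * magnitude, -4, 4)
    return EvidenceSequence(trial_index=trial_index, ie=level / 10.0)


def _pooled_correlation(trials) -> float:
    ie = np.concatenate([t.ie for t in trials])
    ae = np.concatenate([t.simple_ae for t in trials])
    if np.ptp(ie) == 0 or np.ptp(ae) == 0:
        return np.nan
    return float(stats.pearsonr(ie, ae).statistic)


def select_block_sequence(rng_seed, n_candidates: int = N_CANDIDATES,
                          n_trials: int = N_TRIALS_PER_BLOCK,
                          walk_rate: float = WALK_RATE,
                          n_steps: int = N_PAIRS) -> BlockSequence:
    """Generate candidate blocks and keep the one with minimal |corr(IE, AE)|.

    Each candidate pools all of its trials' (IE, simple AE) points into one
    Pearson correlation; the argmin of the absolute correlation is returned,
    ties broken toward the earliest candidate.
    """
    if n_candidates < 1:
        raise ValueError(f"n_candidates must be >= 1, got {n_candidates}")
    rng = as_rng(rng_seed)
    best = None
    for _ in range(n_candidates):
        trials = tuple(
            generate_trial_sequence(rng, walk_rate, n_steps, trial_index=i + 1)
            for i in range(n_trials)
        )
        r = _pooled_correlation(trials)
        key = np.inf if np.isnan(r) else abs(r)
        if best is None or key < best[0]:
            best = (key, BlockSequence(trials=trials, ie_ae_correlation=r))
    return best[1]


def generate_session_sequences(rng_seed, n_blocks: int = 2,
                               n_candidates: int = N_CANDIDATES,
                               n_trials: int = N_TRIALS_PER_BLOCK,
                               walk_rate: float = WALK_RATE,
                               n_steps: int = N_PAIRS) -> list:
    """The block sequences of one session (shared by both tasks)."""
    rng = as_rng(rng_seed)
    return [
        select_block_sequence(rng, n_candidates, n_trials, walk_rate, n_steps)
        for _ in range(n_blocks)
    ]


def sequences_to_frame(blocks) -> pd.DataFrame:
    """Flatten block sequences to the canonical long table.

    Columns: block, trial, pair, ie_level, ie_rescaled, simple_ae, where
    ``simple_ae`` is the running mean on the rescaled -1..+1 scale.
    """
    rows = []
    for b, block in enumerate(blocks, start=1):
        for trial in block.trials:
            ie_r = trial.ie_rescaled
            ae_r = np.cumsum(ie_r) / np.arange(1, ie_r.size + 1)
            for s in range(ie_r.size):
                rows.append((b, trial.trial_index, s + 1,
                             trial.ie[s], ie_r[s], ae_r[s]))
    return pd.DataFrame(
        rows, columns=["block", "trial", "pair", "ie_level", "ie_rescaled",
                       "simple_ae"],
    )
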