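"""Synthetic subjects and slider traces.

Generates populations of subjects with per-task ADM parameters and simulates
their continuous slider reports, reproducing the structure the analysis
assumes: 2 tasks x 2 blocks x 15 trials x 30 pairs per subject, 30 Hz
sampling, pair durations uniform on [1.3, 1.5] s, a majority of
recency-biased subjects, larger averaging noise in the value task, and strong
cross-task consistency of the temporal bias.

The population model works through a Gaussian copula: each subject carries
latent normal traits (bias type, recency strength, primacy strength, log
noise); per-task realisations share a fraction ``cross_task_corr`` of each
trait's variance, and quantile transforms map them onto the configured
marginals.  A subject's bias type (recency vs. primacy) swaps which epsilon
gets the strong Beta marginal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .likelihood import ADMParams, TASKS
from .sequences import (
    EvidenceSequence,
    as_rng,
    generate_session_sequences,
    sequences_to_frame,
)
from .weighting import DEFAULT_ETA, temporal_weight_matrix

__all__ = [
    "PopulationConfig",
    "SubjectSpec",
    "draw_population",
    "simulate_trace",
    "simulate_session",
    "simulate_dataset",
    "generate_ratings",
    "truth_table",
]

SAMPLE_RATE_HZ = 30
PAIR_DURATION_RANGE = (1.3, 1.5)


@dataclass(frozen=True)
class PopulationConfig:
    """Distributions of ADM parameters across synthetic subjects.

    ``recency_fraction`` is the probability that a subject is recency-typed
    (34/38 by default); the strongly expressed epsilon follows
    Beta(*eps_strong*), the weak one Beta(*eps_weak*); log sigma_w is normal
    with a fixed additive offset in the value task; ``cross_task_corr`` is
    the latent correlation tying each trait across the two tasks.
    """

    recency_fraction: float = 34.0 / 38.0
    eps_strong: tuple = (6.0, 2.0)
    eps_weak: tuple = (2.0, 8.0)
    log_sigma_mean: float = -1.0
    log_sigma_sd: float = 0.4
    value_sigma_offset: float = 0.3
    cross_task_corr: float = 0.9
    eta: float = DEFAULT_ETA

    def __post_init__(self):
        if not (0.0 <= self.recency_fraction <= 1.0):
            raise ValueError("recency_fraction must be in [0, 1]")
        if not (0.0 <= self.cross_task_corr <= 1.0):
            raise ValueError("cross_task_corr must be in [0, 1]")
        for name in ("eps_strong", "eps_weak"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValueError(f"{name} Beta parameters must be positive")
        if self.log_sigma_sd < 0:
            raise ValueError("log_sigma_sd must be >= 0")


@dataclass(frozen=True)
class SubjectSpec:
    """A synthetic subject: id, per-task parameters, latent bias score."""

    subject: str
    params: dict  # task -> ADMParams
    bias_score: float  # latent; lower = more recency-typed

    @property
    def is_recency(self) -> dict:
        return {t: p.eps_recency > p.eps_primacy for t, p in self.params.items()}


def _correlated_pair(rng, rho):
    z0 = rng.standard_normal()
    eps = rng.standard_normal(len(TASKS))
    return z0, rho * z0 + np.sqrt(1.0 - rho ** 2) * eps


def draw_population(n_subjects: int, rng_seed,
                    config: PopulationConfig = PopulationConfig()) -> list:
    """Draw ``n_subjects`` subject specs from the population model."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = as_rng(rng_seed)
    rho = config.cross_task_corr
    a_s, b_s = config.eps_strong
    a_w, b_w = config.eps_weak
    subjects = []
    for j in range(n_subjects):
        bias0, bias_t = _correlated_pair(rng, rho)
        _, strong_t = _correlated_pair(rng, rho)
        _, weak_t = _correlated_pair(rng, rho)
        _, noise_t = _correlated_pair(rng, rho)
        params = {}
        for k, task in enumerate(TASKS):
            recency = sps.norm.cdf(bias_t[k]) < config.recency_fraction
            strong = float(sps.beta.ppf(sps.norm.cdf(strong_t[k]), a_s, b_s))
            weak = float(sps.beta.ppf(sps.norm.cdf(weak_t[k]), a_w, b_w))
            eps_r, eps_p = (strong, weak) if recency else (weak, strong)
            log_sw = (config.log_sigma_mean
                      + (config.value_sigma_offset if task == "value" else 0.0)
                      + config.log_sigma_sd * noise_t[k])
            params[task] = ADMParams(eps_p, eps_r, float(np.exp(log_sw)),
                                     config.eta)
        subjects.append(SubjectSpec(subject=f"s{j + 1:02d}", params=params,
                                    bias_score=float(bias0)))
    return subjects


def simulate_trace(seq, params: ADMParams, rng_seed,
                   slider_speed_limit: float | None = None,
                   sample_rate_hz: int = SAMPLE_RATE_HZ,
                   pair_duration_range: tuple = PAIR_DURATION_RANGE,
                   ) -> pd.DataFrame:
    """Simulate one trial's slider samples under the ADM observation model.

    Pair durations are drawn uniformly from ``pair_duration_range``; the
    slider is sampled on the ``sample_rate_hz`` grid from trial onset.  Each
    sample is Normal(mu(t), sigma_w^2 / t) clipped to [-1, +1], where mu is
    the weighted AE of the pairs shown by time t.  With
    ``slider_speed_limit`` set (scale units per second), consecutive samples
    move at most ``limit / rate`` apart, starting from the centre.

    Parameters
    ----------
    seq : EvidenceSequence or ndarray
        The trial's evidence; an EvidenceSequence is rescaled to -1..+1,
        an array is taken as already rescaled.

    Returns
    -------
    DataFrame with columns pair, t_seconds, y.
    """
    rng = as_rng(rng_seed)
    ie = seq.ie_rescaled if isinstance(seq, EvidenceSequence) else np.asarray(seq, float)
    n_pairs = ie.size
    durations = rng.uniform(*pair_duration_range, size=n_pairs)
    offsets = np.concatenate([[0.0], np.cumsum(durations)])
    total = offsets[-1]
    n_samples = int(np.floor(total * sample_rate_hz))
    t = np.arange(1, n_samples + 1) / sample_rate_hz
    pair = np.searchsorted(offsets, t, side="left")
    pair = np.clip(pair, 1, n_pairs)

    W = temporal_weight_matrix(n_pairs, params.eps_primacy, params.eps_recency,
                               params.eta)
    mu_by_pair = (W @ ie) / W.sum(axis=1)
    mu = mu_by_pair[pair - 1]
    sd = params.sigma_w / np.sqrt(t)
    y = np.clip(mu + sd * rng.standard_normal(n_samples), -1.0, 1.0)
    if slider_speed_limit is not None:
        max_step = slider_speed_limit / sample_rate_hz
        prev = 0.0  # slider starts each trial at the centre
        for k in range(n_samples):
            y[k] = prev = np.clip(y[k], prev - max_step, prev + max_step)
    return pd.DataFrame({"pair": pair, "t_seconds": t, "y": y})


def simulate_session(spec: SubjectSpec, blocks, rng_seed,
                     slider_speed_limit: float | None = None) -> pd.DataFrame:
    """Simulate a subject's full session over both tasks and all blocks."""
    rng = as_rng(rng_seed)
    frames = []
    for task in TASKS:
        for b, block in enumerate(blocks, start=1):
            for trial in block.trials:
                tr = simulate_trace(trial, spec.params[task], rng,
                                    slider_speed_limit)
                tr.insert(0, "trial", trial.trial_index)
                tr.insert(0, "block", b)
                tr.insert(0, "task", task)
                tr.insert(0, "subject", spec.subject)
                frames.append(tr)
    return pd.concat(frames, ignore_index=True)


def simulate_dataset(n_subjects: int, rng_seed,
                     config: PopulationConfig = PopulationConfig(),
                     blocks=None, slider_speed_limit: float | None = None):
    """End-to-end synthetic study: sequences, population, traces.

    Returns
    -------
    traces : DataFrame (subject, task, block, trial, pair, t_seconds, y)
    sequences : DataFrame (block, trial, pair, ie_level, ie_rescaled, simple_ae)
    subjects : list of SubjectSpec (the generating truth)
    """
    rng = as_rng(rng_seed)
    if blocks is None:
        blocks = generate_session_sequences(rng)
    subjects = draw_population(n_subjects, rng, config)
    traces = pd.concat(
        [simulate_session(s, blocks, rng, slider_speed_limit) for s in subjects],
        ignore_index=True,
    )
    return traces, sequences_to_frame(blocks), subjects


def generate_ratings(n_items: int = 144, rng_seed=None) -> pd.DataFrame:
    """Synthetic food ratings on the continuous 0-10 scale.

    A clipped Normal(5.5, 2.5) puts most mass mid-scale with a small atom at
    exactly 0 and 10, so the downstream extreme-item exclusions have work to
    do.

    Returns a DataFrame with columns item, rating.
    """
    if n_items < 20:
        raise ValueError("n_items must be >= 20 so the value bins are populable")
    rng = as_rng(rng_seed)
    ratings = np.clip(rng.normal(5.5, 2.5, size=n_items), 0.0, 10.0)
    return pd.DataFrame({
        "item": [f"food{j + 1:03d}" for j in range(n_items)],
        "rating": ratings,
    })


def truth_table(subjects) -> pd.DataFrame:
    """Flatten generating parameters to a tidy frame (one row per task)."""
    rows = []
    for s in subjects:
        for task, p in s.params.items():
            rows.append((s.subject, task, p.eps_primacy, p.eps_recency,
                         p.sigma_w, s.bias_score))
    return pd.DataFrame(rows, columns=[
        "subject", "task", "eps_primacy", "eps_recency", "sigma_w",
        "bias_score",
    ])
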