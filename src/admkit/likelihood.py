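"""ADM observation model and slider-trace likelihood.

The slider position y at time t (seconds since trial onset) is modelled as

    y(t) ~ Normal(mu(t), sigma_w**2 / t)

where mu(t) is the temporally weighted average of the IE presented so far
(held constant between pair onsets) and sigma_w the within-trial noise scale.
The likelihood multiplies the Normal densities of every recorded slider
sample, excluding all samples from the first stimulus pair of each trial
(those reflect the initial joystick ramp, not the estimate).

Four model variants arise from sharing or separating the temporal-bias
parameters (eps_primacy, eps_recency) and the noise parameter (sigma_w)
across the perceptual and value-based tasks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .weighting import (
    DEFAULT_ETA,
    temporal_weight_matrix,
    temporal_weight_matrix_batch,
    weighted_ae,
)

__all__ = [
    "TASKS",
    "ADMParams",
    "ModelVariant",
    "VARIANTS",
    "SubjectData",
    "log_likelihood",
]

TASKS = ("perceptual", "value")
_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ADMParams:
    """Temporal-bias and noise parameters of the ADM (one task)."""

    eps_primacy: float
    eps_recency: float
    sigma_w: float
    eta: float = DEFAULT_ETA

    def __post_init__(self):
        if not (0.0 <= self.eps_primacy <= 1.0):
            raise ValueError(f"eps_primacy must be in [0,1]: {self.eps_primacy}")
        if not (0.0 <= self.eps_recency <= 1.0):
            raise ValueError(f"eps_recency must be in [0,1]: {self.eps_recency}")
        if self.sigma_w <= 0:
            raise ValueError(f"sigma_w must be > 0: {self.sigma_w}")
        if not (0.0 <= self.eta <= 1.0):
            raise ValueError(f"eta must be in [0,1]: {self.eta}")


@dataclass(frozen=True)
class ModelVariant:
    """Sharing structure of bias and noise parameters across the two tasks."""

    bias_sharing: str  # "separate" | "common"
    noise_sharing: str  # "separate" | "common"

    def __post_init__(self):
        for name, v in (("bias_sharing", self.bias_sharing),
                        ("noise_sharing", self.noise_sharing)):
            if v not in ("separate", "common"):
                raise ValueError(f"{name} must be 'separate' or 'common': {v!r}")

    @property
    def label(self) -> str:
        return f"{self.bias_sharing}_bias_{self.noise_sharing}_noise"

    @property
    def param_names(self) -> tuple:
        names = []
        if self.bias_sharing == "separate":
            for task in TASKS:
                names += [f"eps_primacy_{task}", f"eps_recency_{task}"]
        else:
            names += ["eps_primacy", "eps_recency"]
        if self.noise_sharing == "separate":
            names += [f"sigma_w_{task}" for task in TASKS]
        else:
            names += ["sigma_w"]
        return tuple(names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def unpack(self, values, eta: float = DEFAULT_ETA) -> dict:
        """Map a parameter vector (ordered as param_names) to per-task params."""
        values = np.asarray(values, dtype=float)
        if values.size != self.n_params:
            raise ValueError(
                f"expected {self.n_params} values for {self.label}, "
                f"got {values.size}"
            )
        k = 0
        eps = {}
        if self.bias_sharing == "separate":
            for task in TASKS:
                eps[task] = (values[k], values[k + 1])
                k += 2
        else:
            for task in TASKS:
                eps[task] = (values[k], values[k + 1])
            k += 2
        sw = {}
        if self.noise_sharing == "separate":
            for task in TASKS:
                sw[task] = values[k]
                k += 1
        else:
            for task in TASKS:
                sw[task] = values[k]
            k += 1
        return {
            task: ADMParams(eps[task][0], eps[task][1], sw[task], eta)
            for task in TASKS
        }

    def unpack_batch(self, values) -> dict:
        """Map (m, n_params) vectors to task -> (eps_p, eps_r, sigma_w) arrays."""
        v = np.atleast_2d(np.asarray(values, dtype=float))
        cols = dict(zip(self.param_names, v.T))
        out = {}
        for task in TASKS:
            if self.bias_sharing == "separate":
                ep, er = cols[f"eps_primacy_{task}"], cols[f"eps_recency_{task}"]
            else:
                ep, er = cols["eps_primacy"], cols["eps_recency"]
            sw = (cols[f"sigma_w_{task}"] if self.noise_sharing == "separate"
                  else cols["sigma_w"])
            out[task] = (ep, er, sw)
        return out


#: The four variants, ordered simplest first (for WAIC tie-breaking).
VARIANTS = (
    ModelVariant("common", "common"),
    ModelVariant("common", "separate"),
    ModelVariant("separate", "common"),
    ModelVariant("separate", "separate"),
)


class _TaskData:
    """Per-pair sufficient statistics of one subject-task's slider samples.

    For samples within a pair, mu is constant, so the Normal log-likelihood
    reduces to per-pair sums of t, t*y, t*y**2, log t and counts:

        ll = -N/2 log(2 pi sigma_w^2) + 1/2 sum(log t)
             - sum_pairs [Styy - 2 mu Sty + mu^2 St] / (2 sigma_w^2)
    """

    def __init__(self, traces, sequences, n_pairs):
        seq = sequences.sort_values(["block", "trial", "pair"])
        keys = sorted(set(zip(seq["block"], seq["trial"])))
        self.trial_keys = keys
        row_of = {k: r for r, k in enumerate(keys)}
        self.ie = np.full((len(keys), n_pairs), np.nan)
        for (b, l), g in seq.groupby(["block", "trial"]):
            self.ie[row_of[(b, l)], g["pair"].to_numpy() - 1] = (
                g["ie_rescaled"].to_numpy()
            )
        if np.isnan(self.ie).any():
            raise ValueError("sequence table has missing pairs")

        tr = traces
        missing = set(zip(tr["block"], tr["trial"])) - set(keys)
        if missing:
            raise ValueError(
                f"traces reference trials absent from sequences: {sorted(missing)}"
            )
        if (tr["t_seconds"] <= 0).any():
            raise ValueError("sample times must be > 0 seconds")
        if (tr["pair"] > n_pairs).any() or (tr["pair"] < 1).any():
            raise ValueError("trace pair index outside the sequence length")

        inc = tr[tr["pair"] >= 2]  # first-pair samples excluded
        self.t = inc["t_seconds"].to_numpy(dtype=float)
        self.y = inc["y"].to_numpy(dtype=float)
        self.trial_row = np.array(
            [row_of[k] for k in zip(inc["block"], inc["trial"])], dtype=np.intp
        )
        self.pair_idx = inc["pair"].to_numpy(dtype=np.intp) - 1
        self.n_points = self.t.size

        shape = self.ie.shape
        self.N = np.zeros(shape)
        self.St = np.zeros(shape)
        self.Sty = np.zeros(shape)
        self.Styy = np.zeros(shape)
        np.add.at(self.N, (self.trial_row, self.pair_idx), 1.0)
        np.add.at(self.St, (self.trial_row, self.pair_idx), self.t)
        np.add.at(self.Sty, (self.trial_row, self.pair_idx), self.t * self.y)
        np.add.at(self.Styy, (self.trial_row, self.pair_idx),
                  self.t * self.y ** 2)
        self.log_t = np.log(self.t)
        self.sum_log_t = float(self.log_t.sum())
        self.n_pairs = n_pairs

    def mu(self, eps_primacy, eps_recency, eta):
        W = temporal_weight_matrix(self.n_pairs, eps_primacy, eps_recency, eta)
        return (self.ie @ W.T) / W.sum(axis=1)

    def loglik(self, params: ADMParams) -> float:
        if self.n_points == 0:
            return 0.0
        mu = self.mu(params.eps_primacy, params.eps_recency, params.eta)
        quad = np.sum(self.Styy - 2.0 * mu * self.Sty + mu ** 2 * self.St)
        sw2 = params.sigma_w ** 2
        return (-0.5 * self.n_points * (_LOG2PI + np.log(sw2))
                + 0.5 * self.sum_log_t - quad / (2.0 * sw2))

    def pointwise(self, params: ADMParams) -> np.ndarray:
        mu = self.mu(params.eps_primacy, params.eps_recency, params.eta)
        mu_i = mu[self.trial_row, self.pair_idx]
        sw2 = params.sigma_w ** 2
        return (-0.5 * (_LOG2PI + np.log(sw2 / self.t))
                - self.t * (self.y - mu_i) ** 2 / (2.0 * sw2))

    # vectorised twins over m parameter vectors (used by the sampler)

    def _mu_batch(self, eps_p, eps_r, eta):
        W = temporal_weight_matrix_batch(self.n_pairs, eps_p, eps_r, eta)
        return np.einsum("msi,ti->mts", W, self.ie) / W.sum(axis=2)[:, None, :]

    def loglik_batch(self, eps_p, eps_r, sigma_w, eta) -> np.ndarray:
        if self.n_points == 0:
            return np.zeros(np.atleast_1d(eps_p).size)
        mu = self._mu_batch(eps_p, eps_r, eta)
        quad = np.einsum("mts,ts->m",
                         mu * mu, self.St) - 2.0 * np.einsum(
            "mts,ts->m", mu, self.Sty) + self.Styy.sum()
        sw2 = np.atleast_1d(sigma_w) ** 2
        return (-0.5 * self.n_points * (_LOG2PI + np.log(sw2))
                + 0.5 * self.sum_log_t - quad / (2.0 * sw2))

    def pointwise_batch(self, eps_p, eps_r, sigma_w, eta) -> np.ndarray:
        mu = self._mu_batch(eps_p, eps_r, eta)
        mu_i = mu[:, self.trial_row, self.pair_idx]  # (m, n_points)
        sw2 = (np.atleast_1d(sigma_w) ** 2)[:, None]
        resid = self.y[None] - mu_i
        resid *= resid
        resid *= self.t[None] / (2.0 * sw2)
        return (-0.5 * (_LOG2PI + np.log(sw2) - self.log_t[None])) - resid


class SubjectData:
    """One subject's traces and sequences, prepared for fast evaluation."""

    def __init__(self, traces, sequences, n_pairs: int = 30):
        required = {"task", "block", "trial", "pair", "t_seconds", "y"}
        if not required.issubset(traces.columns):
            raise ValueError(f"traces missing columns {required - set(traces.columns)}")
        self.tasks = tuple(t for t in TASKS if (traces["task"] == t).any())
        self.by_task = {
            task: _TaskData(traces[traces["task"] == task], sequences, n_pairs)
            for task in self.tasks
        }
        self.n_points = sum(d.n_points for d in self.by_task.values())
        if self.n_points == 0:
            warnings.warn(
                "no slider samples outside the first stimulus pair: "
                "likelihood is an empty product (0 by convention)",
                stacklevel=2,
            )

    def loglik(self, params_by_task: dict) -> float:
        return sum(self.by_task[task].loglik(params_by_task[task])
                   for task in self.tasks)

    def pointwise(self, params_by_task: dict) -> np.ndarray:
        if self.n_points == 0:
            return np.empty(0)
        return np.concatenate([
            self.by_task[task].pointwise(params_by_task[task])
            for task in self.tasks
        ])

    def loglik_batch(self, arrays_by_task: dict,
                     eta: float = DEFAULT_ETA) -> np.ndarray:
        """Vectorised log-likelihood; arrays as from ``unpack_batch``."""
        total = 0.0
        for task in self.tasks:
            ep, er, sw = arrays_by_task[task]
            total = total + self.by_task[task].loglik_batch(ep, er, sw, eta)
        return total

    def pointwise_batch(self, arrays_by_task: dict,
                        eta: float = DEFAULT_ETA) -> np.ndarray:
        m = np.atleast_1d(arrays_by_task[self.tasks[0]][0]).size
        if self.n_points == 0:
            return np.empty((m, 0))
        return np.concatenate([
            self.by_task[task].pointwise_batch(*arrays_by_task[task], eta)
            for task in self.tasks
        ], axis=1)


def log_likelihood(traces, sequences, params, eta: float = DEFAULT_ETA):
    """Slider-trace log-likelihood, sample by sample (reference path).

    Parameters
    ----------
    traces : DataFrame
        One subject's samples: task, block, trial, pair, t_seconds, y.
    params : ADMParams or dict task -> ADMParams
        A single parameter set applies to every task present.

    Returns
    -------
    total : float
    pointwise : ndarray
        Per-sample log-densities (first-pair samples excluded), summing to
        ``total``.

    Notes
    -----
    This implementation recomputes mu per pair with :func:`weighted_ae`; the
    sampler uses the algebraically equivalent sufficient-statistics path in
    :class:`SubjectData`.
    """
    if isinstance(params, ADMParams):
        params = {task: params for task in TASKS}
    seq_ie = {
        (b, l): g.sort_values("pair")["ie_rescaled"].to_numpy()
        for (b, l), g in sequences.groupby(["block", "trial"])
    }
    terms = []
    for (task, b, l), g in traces.groupby(["task", "block", "trial"]):
        if (b, l) not in seq_ie:
            raise ValueError(f"trial ({b}, {l}) absent from sequences")
        ie = seq_ie[(b, l)]
        p = params[task]
        for s, gp in g.groupby("pair"):
            if s < 2:
                continue
            if s > ie.size:
                raise ValueError(f"pair {s} beyond sequence length {ie.size}")
            mu = weighted_ae(ie[:s], p.eps_primacy, p.eps_recency, p.eta)
            t = gp["t_seconds"].to_numpy(dtype=float)
            sd = p.sigma_w / np.sqrt(t)
            terms.append(sps.norm.logpdf(gp["y"].to_numpy(), mu, sd))
    if not terms:
        warnings.warn("no included slider samples: log-likelihood is 0 "
                      "(empty product)", stacklevel=2)
        return 0.0, np.empty(0)
    pointwise = np.concatenate(terms)
    return float(pointwise.sum()), pointwise
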