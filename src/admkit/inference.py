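"""Bayesian fitting machinery: priors, transforms, sampler, diagnostics.

Parameters are sampled in an unconstrained space (logit for the epsilons,
log for sigma_w) under the priors eps ~ Beta(2, 4) and
log sigma_w ~ Normal(-1, 1).  Sampling uses an affine-invariant ensemble
sampler (emcee); the ensemble's walkers serve as the chains for the
rank-normalised split R-hat diagnostic.  A ``FitConfig`` keeps the familiar
chains x draws accounting: the ensemble uses as many walkers as the
dimensionality requires and runs enough steps that the number of retained
draws matches ``n_chains * n_samples_per_chain``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats as sps
from scipy.special import expit, logit, logsumexp

__all__ = [
    "FitConfig",
    "FitFailureError",
    "WAICResult",
    "rhat",
    "hdi",
    "waic",
    "PointwiseAccumulator",
]


class FitFailureError(RuntimeError):
    """Sampling failed to converge; carries the R-hat diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class FitConfig:
    """MCMC budget, priors and convergence threshold.

    ``n_chains``/``n_samples_per_chain``/``n_warmup`` express the sampling
    budget; the ensemble sampler translates it into walkers x steps with the
    same total number of retained draws.  ``reduced()`` gives the scaled-down
    budget used for simulation studies (2 chains x 1000 draws).
    """

    n_chains: int = 4
    n_warmup: int = 1000
    n_samples_per_chain: int = 4000
    rhat_threshold: float = 1.01
    eps_prior: tuple = (2.0, 4.0)
    log_sigma_prior: tuple = (-1.0, 1.0)
    thin: int = 20
    seed: int | None = None

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 for R-hat")
        if self.rhat_threshold <= 1.0:
            raise ValueError("rhat_threshold must be > 1")
        if self.n_warmup < 0 or self.n_samples_per_chain < 1:
            raise ValueError("invalid sampling budget")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def reduced(cls, seed=None, **kw):
        return cls(n_chains=2, n_warmup=400, n_samples_per_chain=1000,
                   seed=seed, **kw)

    def with_seed(self, seed):
        return replace(self, seed=seed)

    def ensemble_shape(self, ndim: int):
        """(n_walkers, n_warmup_steps, n_run_steps) for dimension ndim.

        The ensemble keeps one draw every ``thin`` steps, so the retained
        draws total ~ n_chains * n_samples_per_chain while the chain runs
        long enough to beat the sampler's autocorrelation time.
        """
        n_walkers = max(self.n_chains, 2 * ndim + 2)
        n_walkers += n_walkers % 2
        kept = int(np.ceil(self.n_chains * self.n_samples_per_chain / n_walkers))
        warm = max(int(np.ceil(self.n_chains * self.n_warmup / n_walkers)), 20)
        return n_walkers, warm * self.thin, kept * self.thin


# ---------------------------------------------------------------------------
# parameter transforms and priors


def is_sigma_param(name: str) -> bool:
    return name.startswith("sigma_w")


def to_unconstrained(values, names):
    x = np.empty(len(names))
    for k, name in enumerate(names):
        x[k] = np.log(values[k]) if is_sigma_param(name) else logit(values[k])
    return x


def to_natural(x, names):
    x = np.atleast_2d(x)
    out = np.empty_like(x, dtype=float)
    for k, name in enumerate(names):
        out[..., k] = (np.exp(x[..., k]) if is_sigma_param(name)
                       else expit(x[..., k]))
    return out if out.shape[0] > 1 else out[0]


def log_prior_unconstrained(x, names, config: FitConfig):
    """Log prior density in the unconstrained space (Jacobians included).

    ``x`` may be a single vector or an (m, ndim) batch.
    """
    a, b = config.eps_prior
    m_, s = config.log_sigma_prior
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    lp = np.zeros(X.shape[0])
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        for k, name in enumerate(names):
            col = X[:, k]
            if is_sigma_param(name):
                lp += sps.norm.logpdf(col, m_, s)  # col = log sigma_w
            else:
                eps = expit(col)
                # Beta(a,b) density plus the logit Jacobian d eps / dx
                lp += sps.beta.logpdf(eps, a, b) + np.log(eps * (1.0 - eps))
    lp = np.where(np.isfinite(lp), lp, -np.inf)
    return float(lp[0]) if single else lp


def sample_prior_natural(names, config: FitConfig, rng, size=None):
    a, b = config.eps_prior
    m, s = config.log_sigma_prior
    cols = []
    for name in names:
        if is_sigma_param(name):
            cols.append(np.exp(rng.normal(m, s, size=size)))
        else:
            cols.append(rng.beta(a, b, size=size))
    return np.stack(cols, axis=-1)


# ---------------------------------------------------------------------------
# sampling


#: coarse natural-scale grids scanned to seed the mode search; the weight
#: function admits local optima (e.g. a near-uniform-weights basin), so the
#: optimiser must start from the best region, not a random prior draw
_EPS_GRID = (0.05, 0.25, 0.5, 0.75, 0.95)
_SIGMA_GRID = (0.15, 0.4, 0.9)


def find_map(log_post, names, config: FitConfig, rng, n_starts: int = 4,
             log_post_batch=None):
    """Posterior mode in unconstrained space.

    Scans the full cartesian grid of plausible parameter values (batched in
    one vectorised call when ``log_post_batch`` is given), then polishes the
    ``n_starts`` best grid points with quasi-Newton optimisation.
    """
    import itertools

    grids = [_SIGMA_GRID if is_sigma_param(n) else _EPS_GRID for n in names]
    mesh = np.array(list(itertools.product(*grids)))
    X = np.stack([to_unconstrained(v, names) for v in mesh])
    if log_post_batch is not None:
        scores = np.asarray(log_post_batch(X))
    else:
        scores = np.array([log_post(x) for x in X])
    starts = X[np.argsort(scores)[-n_starts:]]
    best = None
    for x0 in starts:
        res = optimize.minimize(lambda x: -log_post(x), x0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    return best.x


def run_ensemble(log_post_batch, x0, n_warmup_steps: int, n_run_steps: int,
                 thin: int, rng):
    """Run the affine-invariant ensemble from positions ``x0`` (walkers x ndim).

    ``log_post_batch`` evaluates a whole (m, ndim) batch at once.  Uses a
    differential-evolution move mixture, which mixes faster than the stretch
    move on the narrow, correlated posteriors that arise here.  Returns
    (chain, log_prob) with shapes (walkers, kept, ndim) and (walkers, kept)
    after discarding warmup and keeping every ``thin``-th step.
    """
    import emcee

    n_walkers, ndim = x0.shape
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_post_batch,
                                    moves=moves, vectorize=True)
    seed = int(rng.integers(2 ** 31))
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(x0, n_warmup_steps + n_run_steps, progress=False,
                     skip_initial_state_check=True)
    chain = sampler.get_chain(discard=n_warmup_steps, thin=thin)
    logp = sampler.get_log_prob(discard=n_warmup_steps, thin=thin)
    return np.moveaxis(chain, 0, 1), logp.T


# ---------------------------------------------------------------------------
# diagnostics


def rhat(chains) -> float:
    """Rank-normalised split R-hat of one parameter.

    Parameters
    ----------
    chains : array-like, shape (n_chains, n_draws)
        Posterior draws with at least two chains of equal length.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("rhat needs >= 2 chains of equal length")
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(az.convert_to_dataset(arr))["x"].values)


def hdi(draws, prob: float = 0.95):
    """Shortest contiguous interval containing ``prob`` of the draws."""
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("hdi of empty sample")
    m = int(np.ceil(prob * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


@dataclass(frozen=True)
class WAICResult:
    """WAIC = -2 (lppd - p_waic); lower is better."""

    waic: float
    lppd: float
    p_waic: float
    n_points: int
    n_draws: int


class PointwiseAccumulator:
    """Streaming lppd and p_waic over posterior draws.

    Feeds one draw's pointwise log-likelihood vector at a time, maintaining
    a running log-sum-exp (for lppd) and Welford mean/variance (for p_waic,
    population variance, ddof = 0).
    """

    def __init__(self, n_points: int):
        self.n_points = n_points
        self.n_draws = 0
        self._lse = np.full(n_points, -np.inf)
        self._mean = np.zeros(n_points)
        self._m2 = np.zeros(n_points)

    def add(self, ll: np.ndarray):
        ll = np.asarray(ll, dtype=float)
        if ll.shape != (self.n_points,):
            raise ValueError("pointwise vector has wrong length")
        self.n_draws += 1
        np.logaddexp(self._lse, ll, out=self._lse)
        delta = ll - self._mean
        self._mean += delta / self.n_draws
        self._m2 += delta * (ll - self._mean)

    def add_batch(self, ll: np.ndarray):
        """Fold in a (m, n_points) block of draws (Chan et al. combine)."""
        ll = np.atleast_2d(np.asarray(ll, dtype=float))
        if ll.shape[1] != self.n_points:
            raise ValueError("pointwise block has wrong width")
        m = ll.shape[0]
        if m == 0:
            return
        mx = ll.max(axis=0)
        lse_b = mx + np.log(np.exp(ll - mx).sum(axis=0))
        np.logaddexp(self._lse, lse_b, out=self._lse)
        mean_b = ll.mean(axis=0)
        m2_b = ((ll - mean_b) ** 2).sum(axis=0)
        n_a = self.n_draws
        delta = mean_b - self._mean
        n = n_a + m
        self._mean += delta * (m / n)
        self._m2 += m2_b + delta ** 2 * (n_a * m / n)
        self.n_draws = n

    def result(self) -> WAICResult:
        if self.n_draws == 0 or self.n_points == 0:
            return WAICResult(0.0, 0.0, 0.0, self.n_points, self.n_draws)
        lppd = float(np.sum(self._lse - np.log(self.n_draws)))
        p_waic = float(np.sum(self._m2 / self.n_draws))
        return WAICResult(-2.0 * (lppd - p_waic), lppd, p_waic,
                          self.n_points, self.n_draws)


def waic(pointwise_loglik) -> WAICResult:
    """WAIC from a draws x datapoints matrix of pointwise log-likelihoods.

    lppd_i = log mean_d exp(ll_{d,i}); p_waic_i = Var_d(ll_{d,i}) with the
    population variance convention (ddof = 0).
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2 or ll.size == 0:
        raise ValueError("pointwise log-likelihood must be a nonempty "
                         "draws x datapoints matrix")
    if not np.all(np.isfinite(ll)):
        raise ValueError("pointwise log-likelihood contains non-finite values")
    n_draws, n_points = ll.shape
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(n_draws)))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=0)))
    return WAICResult(-2.0 * (lppd - p_waic), lppd, p_waic, n_points, n_draws)
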