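"""The Averaging Diffusion Model as a fittable model object.

:class:`AveragingDiffusionModel` wraps one subject's slider traces and the
stimulus sequences; ``fit()`` samples the posterior of the chosen variant and
returns an :class:`ADMResults` carrying the draws, convergence diagnostics,
WAIC and posterior summaries.  Module-level helpers fit and compare all four
variants per subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import inference as inf
from .inference import FitConfig, FitFailureError, PointwiseAccumulator
from .likelihood import TASKS, VARIANTS, ModelVariant, SubjectData
from .sequences import as_rng
from .weighting import DEFAULT_ETA

__all__ = [
    "AveragingDiffusionModel",
    "ADMResults",
    "PosteriorSummary",
    "fit_variant",
    "informed_inits",
    "refit_with_informed_inits",
    "compare_variants",
    "summarize_posterior",
]


class AveragingDiffusionModel:
    """ADM likelihood for one subject's data under a sharing variant.

    Parameters
    ----------
    traces : DataFrame
        Slider samples (columns task, block, trial, pair, t_seconds, y);
        may contain a ``subject`` column with a single subject, or pass
        ``subject=`` to select one.
    sequences : DataFrame
        Stimulus sequences (block, trial, pair, ie_rescaled, ...).
    variant : ModelVariant
        Which parameters are shared across the two tasks; defaults to the
        fully separate variant.
    """

    def __init__(self, traces, sequences, variant: ModelVariant = VARIANTS[3],
                 subject=None, eta: float = DEFAULT_ETA, n_pairs: int = 30):
        if subject is not None:
            traces = traces[traces["subject"] == subject]
            if traces.empty:
                raise ValueError(f"no traces for subject {subject!r}")
        elif "subject" in traces.columns:
            ids = traces["subject"].unique()
            if len(ids) > 1:
                raise ValueError(
                    "traces contain multiple subjects; the ADM is fitted per "
                    "subject (pass subject=...)"
                )
            subject = ids[0] if len(ids) else None
        self.subject = subject
        self.variant = variant
        self.eta = eta
        self.data = SubjectData(traces, sequences, n_pairs)
        self.param_names = variant.param_names

    @classmethod
    def from_csv(cls, traces_path, sequences_path, **kwargs):
        from .io import read_sequences, read_traces

        return cls(read_traces(traces_path), read_sequences(sequences_path),
                   **kwargs)

    # -- likelihood / posterior -------------------------------------------

    def loglike(self, values) -> float:
        """Log-likelihood at a natural-scale parameter vector."""
        return self.data.loglik(self.variant.unpack(values, self.eta))

    def loglike_pointwise(self, values) -> np.ndarray:
        return self.data.pointwise(self.variant.unpack(values, self.eta))

    def logpost_unconstrained(self, x, config: FitConfig) -> float:
        lp = inf.log_prior_unconstrained(x, self.param_names, config)
        if not np.isfinite(lp):
            return -np.inf
        ll = self.loglike(inf.to_natural(x, self.param_names))
        return lp + ll if np.isfinite(ll) else -np.inf

    def logpost_batch(self, X, config: FitConfig) -> np.ndarray:
        """Vectorised log posterior over an (m, ndim) unconstrained batch."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        lp = inf.log_prior_unconstrained(X, self.param_names, config)
        natural = inf.to_natural(X, self.param_names)
        natural = np.atleast_2d(natural)
        ll = self.data.loglik_batch(self.variant.unpack_batch(natural),
                                    self.eta)
        out = lp + np.where(np.isfinite(ll), ll, -np.inf)
        return np.where(np.isfinite(out), out, -np.inf)

    def fit_map(self, config: FitConfig = FitConfig(), rng_seed=0) -> dict:
        """Posterior mode (natural scale) via quasi-Newton optimisation."""
        x = inf.find_map(lambda x: self.logpost_unconstrained(x, config),
                         self.param_names, config, as_rng(rng_seed),
                         log_post_batch=lambda X: self.logpost_batch(X,
                                                                     config))
        return dict(zip(self.param_names,
                        inf.to_natural(x, self.param_names)))

    # -- sampling ----------------------------------------------------------

    def fit(self, config: FitConfig = FitConfig(),
            refit_on_divergence: bool = True, strict: bool = False,
            compute_waic: bool = True) -> "ADMResults":
        """Sample the posterior; refit once with informed inits if R-hat
        exceeds the threshold; optionally compute WAIC from the draws."""
        rng = as_rng(config.seed)
        names = self.param_names
        ndim = len(names)
        n_walkers, n_warm, n_kept = config.ensemble_shape(ndim)
        log_post = lambda x: self.logpost_unconstrained(x, config)

        if self.data.n_points > 0:
            center = inf.find_map(
                log_post, names, config, rng,
                log_post_batch=lambda X: self.logpost_batch(X, config))
            x0 = center + 0.05 * rng.standard_normal((n_walkers, ndim))
        else:  # prior-only: start walkers from prior draws
            x0 = np.stack([
                inf.to_unconstrained(v, names)
                for v in inf.sample_prior_natural(names, config, rng,
                                                  size=n_walkers)
            ])
        results = self._sample(x0, config, rng)
        if refit_on_divergence and not results.converged:
            results = refit_with_informed_inits(results, config,
                                                strict=strict)
        elif strict and not results.converged:
            raise FitFailureError("chains did not converge",
                                  diagnostics={"rhat": results.rhat})
        if compute_waic:
            results._compute_waic()
        return results

    def _sample(self, x0, config: FitConfig, rng,
                n_refits: int = 0) -> "ADMResults":
        names = self.param_names
        _, n_warm, n_run = config.ensemble_shape(len(names))
        log_post = lambda X: self.logpost_batch(X, config)
        chain_u, log_prob = inf.run_ensemble(log_post, x0, n_warm, n_run,
                                             config.thin, rng)
        natural = np.empty_like(chain_u)
        for k, name in enumerate(names):
            natural[..., k] = inf.to_natural(
                chain_u[..., k][..., None], [name]
            )[..., 0]
        samples = {name: natural[..., k] for k, name in enumerate(names)}
        rhats = {name: inf.rhat(samples[name]) for name in names}
        return ADMResults(model=self, config=config, samples=samples,
                          log_prob=log_prob, rhat=rhats, n_refits=n_refits)


class ADMResults:
    """Posterior fit of one ADM variant for one subject.

    Attributes
    ----------
    samples : dict
        Parameter name -> draws array (n_chains, n_draws), natural scale.
    log_prob : ndarray
        Log posterior per draw, same layout.
    rhat : dict
        Rank-normalised split R-hat per parameter.
    waic_result : WAICResult or None
    """

    def __init__(self, model, config, samples, log_prob, rhat, n_refits=0):
        self.model = model
        self.variant = model.variant
        self.config = config
        self.samples = samples
        self.log_prob = log_prob
        self.rhat = rhat
        self.n_refits = n_refits
        self.waic_result = None

    # -- basic accessors ---------------------------------------------------

    @property
    def param_names(self):
        return self.model.param_names

    @property
    def converged(self) -> bool:
        return max(self.rhat.values()) <= self.config.rhat_threshold

    @property
    def n_draws(self) -> int:
        return self.log_prob.size

    def draws(self, name) -> np.ndarray:
        """Flattened draws of one parameter or derived quantity.

        Besides the variant's parameters, understands
        ``eps_diff_<task>`` (eps_primacy - eps_recency) and
        ``sigma_w_diff`` (perceptual - value).
        """
        if name in self.samples:
            return self.samples[name].ravel()
        if name == "eps_diff" or name.startswith("eps_diff_"):
            task = name[len("eps_diff_"):] or None
            return (self._task_param("eps_primacy", task)
                    - self._task_param("eps_recency", task))
        if name == "sigma_w_diff":
            return (self._task_param("sigma_w", "perceptual")
                    - self._task_param("sigma_w", "value"))
        raise KeyError(name)

    def _task_param(self, base, task=None) -> np.ndarray:
        if task is not None and f"{base}_{task}" in self.samples:
            return self.samples[f"{base}_{task}"].ravel()
        if base in self.samples:
            return self.samples[base].ravel()
        raise KeyError(f"{base} ({task})")

    @property
    def posterior_mean(self) -> dict:
        return {k: float(v.mean()) for k, v in self.samples.items()}

    def hdi(self, name, prob: float = 0.95):
        return inf.hdi(self.draws(name) if isinstance(name, str) else name,
                       prob)

    def prob_recency(self, task) -> float:
        """Posterior probability that eps_recency exceeds eps_primacy."""
        return float(np.mean(self._task_param("eps_recency", task)
                             > self._task_param("eps_primacy", task)))

    # -- WAIC --------------------------------------------------------------

    def _compute_waic(self, chunk: int = 64):
        model = self.model
        names = self.param_names
        flat = np.stack([self.samples[n].ravel() for n in names], axis=-1)
        acc = PointwiseAccumulator(model.data.n_points)
        for j in range(0, flat.shape[0], chunk):
            block = flat[j:j + chunk]
            acc.add_batch(model.data.pointwise_batch(
                model.variant.unpack_batch(block), model.eta))
        self.waic_result = acc.result()
        return self.waic_result

    @property
    def waic(self) -> float:
        if self.waic_result is None:
            self._compute_waic()
        return self.waic_result.waic

    # -- presentation ------------------------------------------------------

    def summary(self) -> pd.DataFrame:
        """Posterior summary table: mean, sd, 95% HDI, R-hat per parameter."""
        rows = []
        for name in self.param_names:
            d = self.draws(name)
            lo, hi = inf.hdi(d)
            rows.append((name, d.mean(), d.std(ddof=0), lo, hi,
                         self.rhat[name]))
        return pd.DataFrame(
            rows, columns=["param", "mean", "sd", "hdi_2.5%", "hdi_97.5%",
                           "rhat"],
        ).set_index("param")

    def summarize(self) -> "PosteriorSummary":
        return summarize_posterior(self)

    def simulate(self, rng_seed=0, tasks=None) -> pd.DataFrame:
        """Posterior-predictive slider traces for the fitted trials.

        Replays every fitted trial's evidence sequence through the
        observation model at the posterior-mean parameters; useful for
        visual checks of model fit against the observed traces.
        """
        from .simulate import simulate_trace

        rng = as_rng(rng_seed)
        frames = []
        for task in tasks or self.model.data.tasks:
            params = self.model.variant.unpack(
                [self.posterior_mean[n] for n in self.param_names],
                self.model.eta)[task]
            td = self.model.data.by_task[task]
            for row, (b, l) in enumerate(td.trial_keys):
                tr = simulate_trace(td.ie[row], params, rng)
                tr.insert(0, "trial", l)
                tr.insert(0, "block", b)
                tr.insert(0, "task", task)
                tr.insert(0, "subject", self.model.subject)
                frames.append(tr)
        return pd.concat(frames, ignore_index=True)

    def plot_weighting_curve(self, task="perceptual", s_t: int = 30, ax=None):
        """Plot the posterior-mean temporal weighting function."""
        import matplotlib.pyplot as plt

        from .weighting import temporal_weight

        if ax is None:
            _, ax = plt.subplots()
        eps_p = float(self._task_param("eps_primacy", task).mean())
        eps_r = float(self._task_param("eps_recency", task).mean())
        i = np.arange(1, s_t + 1)
        ax.plot(i, temporal_weight(i, s_t, eps_p, eps_r, self.model.eta))
        ax.set(xlabel="stimulus pair", ylabel="weight", ylim=(0, 1.05),
               title=f"temporal weighting ({task})")
        return ax

    def __repr__(self):
        return (f"<ADMResults {self.variant.label} subject="
                f"{self.model.subject!r} draws={self.n_draws} "
                f"converged={self.converged}>")


@dataclass(frozen=True)
class PosteriorSummary:
    """Digest of a fit: bias direction, HDIs and posterior probabilities."""

    posterior_means: dict
    eps_diff_hdi: dict  # task -> (lo, hi) of eps_primacy - eps_recency
    prob_recency: dict  # task -> P(eps_recency > eps_primacy)
    classification: dict  # task -> "recency" | "primacy" | "indeterminate"
    sigma_w_diff_hdi: tuple | None  # perceptual - value, separate noise only


def summarize_posterior(fit: ADMResults) -> PosteriorSummary:
    """Classify temporal bias from the posterior of eps_primacy - eps_recency.

    A task is classified "recency" when the 95% HDI of the difference is
    strictly negative, "primacy" when strictly positive, else
    "indeterminate".
    """
    eps_diff_hdi, prob, cls = {}, {}, {}
    for task in TASKS:
        d = (fit._task_param("eps_primacy", task)
             - fit._task_param("eps_recency", task))
        lo, hi = inf.hdi(d)
        eps_diff_hdi[task] = (lo, hi)
        prob[task] = fit.prob_recency(task)
        cls[task] = ("recency" if hi < 0.0
                     else "primacy" if lo > 0.0 else "indeterminate")
    sig = None
    if fit.variant.noise_sharing == "separate":
        sig = inf.hdi(fit.draws("sigma_w_diff"))
    return PosteriorSummary(posterior_means=fit.posterior_mean,
                            eps_diff_hdi=eps_diff_hdi, prob_recency=prob,
                            classification=cls, sigma_w_diff_hdi=sig)


def fit_variant(traces, sequences, variant: ModelVariant,
                config: FitConfig = FitConfig(), subject=None,
                **fit_kwargs) -> ADMResults:
    """Fit one sharing variant to one subject's traces."""
    model = AveragingDiffusionModel(traces, sequences, variant,
                                    subject=subject)
    return model.fit(config, **fit_kwargs)


def informed_inits(fit: ADMResults, n_walkers: int, rng) -> np.ndarray:
    """Natural-scale walker inits from the best chain's marginal 95% HDIs.

    The best chain is the one whose maximum log posterior is highest; each
    parameter's initial values are drawn independently and uniformly within
    that chain's 95% HDI.
    """
    names = fit.model.param_names
    best_chain = int(np.argmax(fit.log_prob.max(axis=1)))
    return np.stack([
        rng.uniform(*inf.hdi(fit.samples[name][best_chain]), size=n_walkers)
        for name in names
    ], axis=-1)


def refit_with_informed_inits(fit: ADMResults, config: FitConfig = None,
                              strict: bool = True) -> ADMResults:
    """Refit a nonconvergent fit from informed initial values.

    Picks the chain with the highest log posterior, draws each chain's
    initial value for each parameter independently and uniformly within that
    chain's marginal 95% HDI, and reruns the sampler.  A converged fit is
    returned unchanged.  If the refit is also nonconvergent, raises
    :class:`FitFailureError` (``strict=True``) or returns the refit with a
    warning.
    """
    config = config or fit.config
    if fit.converged:
        return fit
    model = fit.model
    names = model.param_names
    rng = as_rng(None if config.seed is None else config.seed + 1)
    n_walkers, _, _ = config.ensemble_shape(len(names))
    nat0 = informed_inits(fit, n_walkers, rng)
    x0 = np.stack([inf.to_unconstrained(v, names) for v in nat0])
    refit = model._sample(x0, config, rng, n_refits=fit.n_refits + 1)
    if not refit.converged:
        diag = {"rhat_first": fit.rhat, "rhat_refit": refit.rhat}
        if strict:
            raise FitFailureError(
                "refit with informed inits did not converge", diag)
        warnings.warn(f"refit did not converge: {diag}", stacklevel=2)
    return refit


def compare_variants(fits) -> tuple:
    """Select the preferred variant by WAIC (lower is better).

    Ties are broken toward the variant with fewer parameters.  Accepts the
    fits in any order and returns ``(selected_variant, table)`` where the
    table has one row per fit with WAIC components.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    rows = []
    for f in fits:
        w = f.waic_result or f._compute_waic()
        rows.append((f.variant.label, w.waic, w.lppd, w.p_waic,
                     f.variant.n_params, f.converged))
    table = pd.DataFrame(rows, columns=[
        "variant", "waic", "lppd", "p_waic", "n_params", "converged",
    ])
    order = np.lexsort((table["n_params"].to_numpy(),
                        table["waic"].to_numpy()))
    best = fits[int(order[0])]
    return best.variant, table.sort_values(
        ["waic", "n_params"], kind="stable").reset_index(drop=True)
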