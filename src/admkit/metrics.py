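"""Model-free behavioral statistics of evidence-averaging performance.

Mean error (ME) measures how far the final slider position of each stimulus
pair sits from the running simple average of the evidence; the deviance
index d_a compares total deviation from the instantaneous evidence against
total deviation from the simple average (0 = pure IE reporting, larger =
better AE tracking).  Two cluster-robust regressions probe how tracking
error and evidence sensitivity evolve within a trial, and cross-task
correlations quantify the within-subject consistency of these measures.
All quantities operate on the rescaled -1..+1 slider scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

from .weighting import DEFAULT_ETA, temporal_weight

__all__ = [
    "last_positions",
    "mean_error",
    "deviance_index",
    "error_regression",
    "update_regression",
    "weighting_curve",
    "cross_task_correlation",
    "bonus_payoff",
    "RegressionResult",
    "behavioral_summary",
]

BONUS_MAX, BONUS_MIN = 10.0, 1.0
BONUS_DEV_LO, BONUS_DEV_HI = 0.04, 0.20


class RegressionResult:
    """OLS estimates with cluster-robust (subject-level) standard errors."""

    def __init__(self, fit, clustering: str, metadata: dict):
        self._fit = fit
        self.clustering = clustering
        self.metadata = metadata

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "beta": self._fit.params,
            "se": self._fit.bse,
            "p": self._fit.pvalues,
        })

    def __getitem__(self, term):
        return float(self._fit.params[term])

    def __repr__(self):
        return f"<RegressionResult terms={list(self._fit.params.index)}>"


def last_positions(traces, sequences) -> pd.DataFrame:
    """Final slider position of every stimulus pair, joined with the
    sequence's IE and simple AE (rescaled scale).

    Raises if any (subject, task, block, trial) misses pairs relative to the
    sequence table.
    """
    tr = traces.sort_values(["subject", "task", "block", "trial", "t_seconds"])
    last = (tr.groupby(["subject", "task", "block", "trial", "pair"],
                       as_index=False, sort=True)
              .last())
    merged = last.merge(sequences[["block", "trial", "pair", "ie_rescaled",
                                   "simple_ae"]],
                        on=["block", "trial", "pair"], how="left",
                        validate="many_to_one")
    if merged["ie_rescaled"].isna().any():
        bad = merged.loc[merged["ie_rescaled"].isna(),
                         ["block", "trial", "pair"]].drop_duplicates()
        raise ValueError(f"trace pairs absent from sequences:\n{bad}")
    n_pairs = sequences.groupby(["block", "trial"])["pair"].nunique()
    counts = merged.groupby(["subject", "task", "block", "trial"])["pair"].nunique()
    expected = counts.index.map(lambda k: n_pairs[(k[2], k[3])])
    gaps = counts[counts != expected]
    if len(gaps):
        raise ValueError(f"missing stimulus pairs in traces:\n{gaps}")
    return merged


def mean_error(traces, sequences) -> pd.DataFrame:
    """Mean absolute deviation of final pair positions from the simple AE.

    Returns one row per subject x task with column ``me``; all pairs of all
    trials enter (including the first pair of each trial).
    """
    lp = last_positions(traces, sequences)
    lp["abs_err"] = (lp["y"] - lp["simple_ae"]).abs()
    return (lp.groupby(["subject", "task"], as_index=False)["abs_err"]
              .mean().rename(columns={"abs_err": "me"}))


def deviance_index(traces, sequences) -> pd.DataFrame:
    """Ratio of total |y - IE| to total |y - simple AE| per subject x task.

    A pure IE reporter scores 0; a perfect AE tracker has a zero denominator
    and is reported as +inf with a warning.
    """
    lp = last_positions(traces, sequences)
    lp["num"] = (lp["y"] - lp["ie_rescaled"]).abs()
    lp["den"] = (lp["y"] - lp["simple_ae"]).abs()
    g = lp.groupby(["subject", "task"], as_index=False)[["num", "den"]].sum()
    zero = g["den"] == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} subject-task cell(s) have zero deviation "
            "from the simple AE; deviance index reported as +inf",
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        g["d_a"] = np.where(zero, np.inf, g["num"] / g["den"])
    return g[["subject", "task", "d_a"]]


def _regression_frame(traces, sequences, time_unit: str) -> pd.DataFrame:
    lp = last_positions(traces, sequences)
    if time_unit == "pair":
        lp["time"] = lp["pair"].astype(float)
    elif time_unit == "seconds":
        lp["time"] = lp["t_seconds"].astype(float)
    else:
        raise ValueError("time_unit must be 'pair' or 'seconds'")
    lp["task_value"] = (lp["task"] == "value").astype(float)
    return lp


def _clustered_fit(formula, df):
    """OLS with subject-clustered SEs; heteroskedasticity-robust fallback
    when only one cluster is present (clustering is then undefined)."""
    model = smf.ols(formula, data=df)
    if df["subject"].nunique() >= 2:
        fit = model.fit(cov_type="cluster",
                        cov_kwds={"groups": df["subject"]})
        cov = "cluster-robust (CR1 small-sample correction)"
    else:
        fit = model.fit(cov_type="HC1")
        cov = "HC1 (single subject: clustering undefined)"
    return fit, cov


def error_regression(traces, sequences,
                     time_unit: str = "pair") -> RegressionResult:
    """Regress per-pair tracking error on time, task type and interaction.

    The dependent variable is |y - simple AE| per stimulus pair; time is the
    pair index (1-30) by default; task is coded 1 = value-based,
    0 = perceptual; standard errors are clustered at the subject level.
    """
    df = _regression_frame(traces, sequences, time_unit)
    df["abs_err"] = (df["y"] - df["simple_ae"]).abs()
    fit, cov = _clustered_fit("abs_err ~ time * task_value", df)
    return RegressionResult(fit, clustering="subject", metadata={
        "dependent": "|y - simple_ae| per pair",
        "task_coding": "1 = value-based, 0 = perceptual",
        "time_unit": time_unit,
        "cov": cov,
    })


def update_regression(traces, sequences,
                      time_unit: str = "pair") -> RegressionResult:
    """Regress AE updates on IE, time, task type and all interactions.

    The dependent variable is the change in final slider position between
    consecutive pairs (y_s - y_{s-1}, s >= 2); the first pair of each trial
    contributes no update.  Clustered standard errors as in
    :func:`error_regression`.
    """
    df = _regression_frame(traces, sequences, time_unit)
    df = df.sort_values(["subject", "task", "block", "trial", "pair"])
    df["dy"] = df.groupby(["subject", "task", "block", "trial"])["y"].diff()
    df = df.rename(columns={"ie_rescaled": "ie"}).dropna(subset=["dy"])
    fit, cov = _clustered_fit("dy ~ ie * time * task_value", df)
    return RegressionResult(fit, clustering="subject", metadata={
        "dependent": "y_s - y_{s-1} (s >= 2)",
        "task_coding": "1 = value-based, 0 = perceptual",
        "time_unit": time_unit,
        "cov": cov,
    })


def weighting_curve(params, s_t: int = 30, eta: float = None) -> np.ndarray:
    """Temporal weighting function at the ``s_t``-th stimulus pair.

    ``params`` is one ADMParams (or anything with eps_primacy/eps_recency
    and eta) or an iterable of them, in which case the curves are averaged
    across subjects.
    """
    try:
        plist = list(params)
    except TypeError:
        plist = [params]
    i = np.arange(1, s_t + 1)
    curves = [
        temporal_weight(i, s_t, p.eps_primacy, p.eps_recency,
                        eta if eta is not None else getattr(p, "eta", DEFAULT_ETA))
        for p in plist
    ]
    return np.mean(curves, axis=0)


def cross_task_correlation(values: pd.DataFrame, column: str = None):
    """Pearson correlation of a per-subject measure across the two tasks.

    ``values`` has columns subject, task and the measure (the only remaining
    column, or named by ``column``).  Pairwise-complete: subjects with a
    non-finite value in either task are dropped.

    Returns ``(r, n)`` where n is the number of complete subjects.
    """
    if column is None:
        extra = [c for c in values.columns if c not in ("subject", "task")]
        if len(extra) != 1:
            raise ValueError(f"ambiguous measure columns {extra}")
        column = extra[0]
    wide = values.pivot(index="subject", columns="task", values=column)
    wide = wide.replace([np.inf, -np.inf], np.nan).dropna()
    if wide.shape[1] != 2 or len(wide) < 3:
        raise ValueError("need both tasks and >= 3 complete subjects")
    r = sps.pearsonr(wide.iloc[:, 0], wide.iloc[:, 1]).statistic
    return float(r), len(wide)


def bonus_payoff(mean_deviation_fraction):
    """Bonus in dollars from the mean slider deviation (fraction of scale).

    Deviations up to 4% of the scale length earn the $10 maximum, 20% or
    more the $1 minimum, with linear interpolation in between.
    """
    d = np.asarray(mean_deviation_fraction, dtype=float)
    if np.any(d < 0):
        raise ValueError("deviation fraction must be >= 0")
    out = np.interp(d, [BONUS_DEV_LO, BONUS_DEV_HI], [BONUS_MAX, BONUS_MIN])
    return out[()] if out.ndim == 0 else out


def behavioral_summary(traces, sequences) -> dict:
    """ME, deviance index and their cross-task correlations in one pass.

    Infinite deviance indices are excluded from group means (with a count
    of exclusions in the output).
    """
    me = mean_error(traces, sequences)
    da = deviance_index(traces, sequences)
    finite = da[np.isfinite(da["d_a"])]
    out = {
        "me": me,
        "d_a": da,
        "me_by_task": me.groupby("task")["me"].mean().to_dict(),
        "d_a_by_task": finite.groupby("task")["d_a"].mean().to_dict(),
        "d_a_infinite_excluded": int((~np.isfinite(da["d_a"])).sum()),
    }
    try:
        out["me_cross_task_r"], out["n_me"] = cross_task_correlation(me)
        out["d_a_cross_task_r"], out["n_d_a"] = cross_task_correlation(da)
    except ValueError:
        pass
    return out
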