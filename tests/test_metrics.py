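import numpy as np
import pandas as pd
import pytest

from admkit import (
    ADMParams,
    bonus_payoff,
    behavioral_summary,
    cross_task_correlation,
    deviance_index,
    error_regression,
    mean_error,
    simulate_trace,
    temporal_weight,
    update_regression,
    weighting_curve,
)
from conftest import toy_tables


def brute_force_me_da(traces, sequences):
    """Independent recomputation of ME and d_a straight off the raw rows."""
    seq = {(r.block, r.trial, r.pair): (r.ie_rescaled, r.simple_ae)
           for r in sequences.itertuples()}
    last = {}
    for r in traces.sort_values("t_seconds").itertuples():
        last[(r.subject, r.task, r.block, r.trial, r.pair)] = r.y
    me, da = {}, {}
    acc = {}
    for (sub, task, b, l, s), y in last.items():
        ie, ae = seq[(b, l, s)]
        cell = acc.setdefault((sub, task), [0.0, 0.0, 0])
        cell[0] += abs(y - ie)
        cell[1] += abs(y - ae)
        cell[2] += 1
    for (sub, task), (num, den, n) in acc.items():
        me[(sub, task)] = den / n
        da[(sub, task)] = num / den if den > 0 else np.inf
    return me, da


class TestMeanErrorAndDeviance:
    def test_two_pair_toy_by_hand(self):
        traces, sequences = toy_tables()
        me = mean_error(traces, sequences)
        assert me.me.iloc[0] == pytest.approx(0.15)
        da = deviance_index(traces, sequences)
        assert da.d_a.iloc[0] == pytest.approx(1.0)

    def test_perfect_ae_tracker(self):
        traces, sequences = toy_tables()
        traces = traces.assign(y=sequences.simple_ae.to_numpy())
        assert mean_error(traces, sequences).me.iloc[0] == 0.0
        with pytest.warns(UserWarning, match="zero deviation"):
            da = deviance_index(traces, sequences)
        assert np.isinf(da.d_a.iloc[0])

    def test_pure_ie_reporter_scores_zero(self):
        traces, sequences = toy_tables()
        traces = traces.assign(y=sequences.ie_rescaled.to_numpy())
        assert deviance_index(traces, sequences).d_a.iloc[0] == 0.0

    def test_matches_independent_recomputation(self, small_dataset):
        traces, sequences, _ = small_dataset
        me = mean_error(traces, sequences)
        da = deviance_index(traces, sequences)
        bme, bda = brute_force_me_da(traces, sequences)
        for r in me.itertuples():
            assert r.me == pytest.approx(bme[(r.subject, r.task)], abs=1e-12)
        for r in da.itertuples():
            assert r.d_a == pytest.approx(bda[(r.subject, r.task)], abs=1e-12)

    def test_missing_pairs_reported(self, small_dataset):
        traces, sequences, _ = small_dataset
        broken = traces[~((traces.trial == 2) & (traces.pair == 17))]
        with pytest.raises(ValueError, match="missing"):
            mean_error(broken, sequences)

    def test_deviance_decreases_with_recency_strength(self, small_sequences,
                                                      small_blocks):
        # under (near-)pure recency the weights decay geometrically from the
        # newest item with ratio eps_recency, so SMALLER eps_recency means a
        # sharper decay, i.e. stronger recency; stronger recency tracks the
        # IE more closely and drives d_a down.  (For eps_recency below ~0.4
        # the eta floor takes over and re-introduces averaging, so the sweep
        # stays above that.)
        rng_seed = 21
        das = []
        for eps_r in (0.95, 0.8, 0.6):  # increasing recency strength
            frames = []
            for trial in small_blocks[0].trials:
                tr = simulate_trace(trial, ADMParams(0.05, eps_r, 0.05),
                                    rng_seed)
                tr.insert(0, "trial", trial.trial_index)
                tr.insert(0, "block", 1)
                tr.insert(0, "task", "perceptual")
                tr.insert(0, "subject", "s1")
                frames.append(tr)
            da = deviance_index(pd.concat(frames), small_sequences)
            das.append(da.d_a.iloc[0])
        assert das[0] > das[1] > das[2]

    def test_me_increases_with_noise(self, small_blocks, small_sequences):
        mes = []
        for sw in (0.05, 0.3, 0.9):
            frames = []
            for trial in small_blocks[0].trials:
                tr = simulate_trace(trial, ADMParams(0.05, 1.0, sw), 13)
                tr.insert(0, "trial", trial.trial_index)
                tr.insert(0, "block", 1)
                tr.insert(0, "task", "perceptual")
                tr.insert(0, "subject", "s1")
                frames.append(tr)
            mes.append(mean_error(pd.concat(frames),
                                  small_sequences).me.iloc[0])
        assert mes[0] < mes[1] < mes[2]


class TestRegressions:
    @staticmethod
    def _exact_linear_tables():
        rows = []
        for task, (a, b) in (("perceptual", (0.01, 0.003)),
                             ("value", (0.03, 0.001))):
            for sub in ("s1", "s2"):
                for trial in (1, 2):
                    for s in range(1, 31):
                        rows.append((sub, task, 1, trial, s, float(s),
                                     0.0 + a + b * s))
        traces = pd.DataFrame(rows, columns=["subject", "task", "block",
                                             "trial", "pair", "t_seconds",
                                             "y"])
        seq = pd.DataFrame({
            "block": 1, "trial": np.repeat([1, 2], 30),
            "pair": np.tile(np.arange(1, 31), 2),
            "ie_level": 0.0, "ie_rescaled": 0.0, "simple_ae": 0.0,
        })
        return traces, seq

    def test_exact_linear_error_recovered(self):
        traces, seq = self._exact_linear_tables()
        res = error_regression(traces, seq)
        t = res.table
        assert res["time"] == pytest.approx(0.003, abs=1e-10)
        assert res["Intercept"] == pytest.approx(0.01, abs=1e-10)
        assert res["task_value"] == pytest.approx(0.02, abs=1e-10)
        assert res["time:task_value"] == pytest.approx(-0.002, abs=1e-10)
        assert (t.se < 1e-8).all()
        assert res.metadata["task_coding"].startswith("1 = value")

    def test_constant_slider_gives_null_update_regression(self):
        traces, seq = self._exact_linear_tables()
        traces = traces.assign(y=0.25)
        res = update_regression(traces, seq)
        np.testing.assert_allclose(res.table.beta, 0.0, atol=1e-12)

    def test_update_regression_excludes_first_pair(self):
        traces, seq = self._exact_linear_tables()
        res = update_regression(traces, seq)
        # 2 subjects x 2 tasks x 2 trials x 29 updates
        assert res._fit.nobs == 2 * 2 * 2 * 29

    def test_simulated_averager_signs(self, small_blocks, small_sequences):
        # an unbiased averager updates by (IE - AE)/N_s: positive IE effect
        # shrinking with time
        frames = []
        rng = np.random.default_rng(17)
        for task in ("perceptual", "value"):
            for trial in small_blocks[0].trials:
                tr = simulate_trace(trial, ADMParams(0.05, 1.0, 0.02), rng)
                tr.insert(0, "trial", trial.trial_index)
                tr.insert(0, "block", 1)
                tr.insert(0, "task", task)
                tr.insert(0, "subject", "s1")
                frames.append(tr)
        res = update_regression(pd.concat(frames), small_sequences)
        assert res["ie"] > 0
        assert res["ie:time"] < 0


class TestWeightingCurve:
    def test_matches_temporal_weight_elementwise(self):
        p = ADMParams(0.2, 0.7, 0.5)
        curve = weighting_curve(p, s_t=30)
        np.testing.assert_allclose(
            curve, temporal_weight(np.arange(1, 31), 30, 0.2, 0.7))

    def test_flat_at_baseline_without_bias(self):
        np.testing.assert_allclose(
            weighting_curve(ADMParams(0.0, 0.0, 1.0)), 0.01)

    def test_recency_curve_increasing_and_averaging(self):
        ps = [ADMParams(0.0, 0.6, 1.0), ADMParams(0.0, 0.9, 1.0)]
        avg = weighting_curve(ps)
        assert np.all(np.diff(avg) > 0)
        np.testing.assert_allclose(
            avg, (weighting_curve(ps[0]) + weighting_curve(ps[1])) / 2)


class TestCrossTaskCorrelation:
    @staticmethod
    def _frame(vals_p, vals_v):
        n = len(vals_p)
        return pd.DataFrame({
            "subject": [f"s{i}" for i in range(n)] * 2,
            "task": ["perceptual"] * n + ["value"] * n,
            "d_a": list(vals_p) + list(vals_v),
        })

    def test_identical_and_anticorrelated(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, n = cross_task_correlation(self._frame(x, x))
        assert r == pytest.approx(1.0) and n == 4
        r, _ = cross_task_correlation(self._frame(x, [-v for v in x]))
        assert r == pytest.approx(-1.0)

    def test_infinite_values_dropped_pairwise(self):
        x = [1.0, 2.0, 3.0, np.inf, 5.0]
        r, n = cross_task_correlation(self._frame(x, x))
        assert n == 4 and r == pytest.approx(1.0)


class TestBonusPayoff:
    @pytest.mark.parametrize("dev,expected", [
        (0.03, 10.0), (0.04, 10.0), (0.12, 5.5), (0.20, 1.0), (0.25, 1.0),
    ])
    def test_schedule(self, dev, expected):
        assert bonus_payoff(dev) == pytest.approx(expected)

    def test_vectorized_and_validated(self):
        np.testing.assert_allclose(bonus_payoff([0.0, 0.12, 1.0]),
                                   [10.0, 5.5, 1.0])
        with pytest.raises(ValueError):
            bonus_payoff(-0.01)


def test_behavioral_summary_bundles_everything(small_dataset):
    traces, sequences, _ = small_dataset
    s = behavioral_summary(traces, sequences)
    assert set(s["me_by_task"]) == {"perceptual", "value"}
    assert s["d_a_infinite_excluded"] == 0
    assert -1.0 <= s["d_a_cross_task_r"] <= 1.0
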