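import numpy as np
import pytest

from admkit import (
    ADMResults,
    AveragingDiffusionModel,
    FitConfig,
    VARIANTS,
    compare_variants,
    refit_with_informed_inits,
    summarize_posterior,
)
from admkit.inference import WAICResult, hdi
from admkit.model import informed_inits

TINY = FitConfig(n_chains=2, n_warmup=100, n_samples_per_chain=300, thin=5,
                 seed=31)


@pytest.fixture(scope="module")
def fitted(small_dataset):
    traces, sequences, subjects = small_dataset
    spec = subjects[0]
    model = AveragingDiffusionModel(traces, sequences, VARIANTS[3],
                                    subject=spec.subject)
    res = model.fit(TINY, refit_on_divergence=False, compute_waic=False)
    return spec, res


class TestFit:
    def test_posterior_concentrates_near_truth(self, fitted):
        spec, res = fitted
        for task in ("perceptual", "value"):
            truth = spec.params[task]
            post = res.posterior_mean
            got_diff = (post[f"eps_recency_{task}"]
                        - post[f"eps_primacy_{task}"])
            true_diff = truth.eps_recency - truth.eps_primacy
            assert np.sign(got_diff) == np.sign(true_diff)
            assert post[f"sigma_w_{task}"] == pytest.approx(truth.sigma_w,
                                                            rel=0.2)

    def test_summary_table_structure(self, fitted):
        _, res = fitted
        table = res.summary()
        assert list(table.columns) == ["mean", "sd", "hdi_2.5%", "hdi_97.5%",
                                       "rhat"]
        assert list(table.index) == list(res.param_names)
        assert (table["hdi_2.5%"] <= table["hdi_97.5%"]).all()
        assert (table["rhat"] >= 0.99).all()

    def test_seeded_fit_is_reproducible(self, small_dataset):
        traces, sequences, subjects = small_dataset
        kw = dict(refit_on_divergence=False, compute_waic=False)
        fits = [
            AveragingDiffusionModel(
                traces, sequences, VARIANTS[0],
                subject=subjects[1].subject).fit(TINY, **kw)
            for _ in range(2)
        ]
        for name in fits[0].param_names:
            np.testing.assert_array_equal(fits[0].samples[name],
                                          fits[1].samples[name])

    def test_multiple_subjects_rejected(self, small_dataset):
        traces, sequences, _ = small_dataset
        with pytest.raises(ValueError, match="per .?subject"):
            AveragingDiffusionModel(traces, sequences)

    def test_prior_only_fit_recovers_prior(self, small_sequences):
        import pandas as pd

        # only first-pair samples -> empty likelihood -> posterior == prior
        traces = pd.DataFrame({
            "subject": "s1", "task": "perceptual", "block": 1, "trial": 1,
            "pair": 1, "t_seconds": np.arange(1, 11) / 30.0,
            "y": np.zeros(10),
        })
        with pytest.warns(UserWarning):
            model = AveragingDiffusionModel(traces, small_sequences,
                                            VARIANTS[0])
        res = model.fit(FitConfig(n_chains=2, n_warmup=200,
                                  n_samples_per_chain=1000, thin=5, seed=5),
                        refit_on_divergence=False, compute_waic=False)
        assert res.posterior_mean["eps_primacy"] == pytest.approx(1 / 3,
                                                                  abs=0.05)
        assert res.posterior_mean["eps_recency"] == pytest.approx(1 / 3,
                                                                  abs=0.05)
        assert np.median(res.draws("sigma_w")) == pytest.approx(np.exp(-1),
                                                                abs=0.07)


class TestPosteriorPredictive:
    def test_simulated_traces_mirror_fitted_trials(self, fitted):
        _, res = fitted
        sim = res.simulate(rng_seed=1, tasks=("perceptual",))
        assert set(sim.task) == {"perceptual"}
        counts = sim.groupby(["block", "trial"])["pair"].nunique()
        assert (counts == 30).all()
        assert sim["y"].abs().max() <= 1.0

    def test_weighting_curve_plot(self, fitted):
        import matplotlib

        matplotlib.use("Agg")
        _, res = fitted
        ax = res.plot_weighting_curve(task="value")
        assert ax.get_ylabel() == "weight"
        assert len(ax.lines) == 1


class TestSummaries:
    def test_strong_recency_classification(self, fitted):
        spec, res = fitted
        ps = summarize_posterior(res)
        for task in ("perceptual", "value"):
            truth = spec.params[task]
            if truth.eps_recency - truth.eps_primacy > 0.3:
                assert ps.classification[task] == "recency"
                assert ps.prob_recency[task] > 0.99
            lo, hi = ps.eps_diff_hdi[task]
            assert lo <= hi
        assert ps.sigma_w_diff_hdi is not None

    def test_all_recency_draws_probability_one(self, fitted):
        _, res = fitted
        # doctored results: recency draws strictly above primacy draws
        doctored = ADMResults(
            model=res.model, config=res.config,
            samples={**res.samples,
                     "eps_primacy_perceptual": np.full((2, 50), 0.1),
                     "eps_recency_perceptual": np.full((2, 50), 0.9)},
            log_prob=res.log_prob, rhat=res.rhat)
        assert doctored.prob_recency("perceptual") == 1.0

    def test_symmetric_draws_are_indeterminate(self, fitted):
        _, res = fitted
        sym = np.tile(np.linspace(0.1, 0.9, 100), (2, 1))
        doctored = ADMResults(
            model=res.model, config=res.config,
            samples={**res.samples,
                     "eps_primacy_value": sym, "eps_recency_value": sym[:, ::-1]},
            log_prob=res.log_prob, rhat=res.rhat)
        ps = summarize_posterior(doctored)
        assert ps.classification["value"] == "indeterminate"
        assert ps.prob_recency["value"] == pytest.approx(0.5, abs=0.02)


class _StubFit:
    def __init__(self, variant, waic):
        self.variant = variant
        self.waic_result = WAICResult(waic, 0.0, 0.0, 1, 1)
        self.converged = True


class TestCompareVariants:
    def test_argmin_selection(self):
        fits = [_StubFit(v, w) for v, w in zip(VARIANTS, [12.0, 10.0, 16.0,
                                                          14.0])]
        selected, table = compare_variants(fits)
        assert selected == VARIANTS[1]
        assert len(table) == 4
        assert table.iloc[0]["waic"] == 10.0

    def test_tie_broken_toward_simpler_variant(self):
        fits = [_StubFit(VARIANTS[3], 10.0), _StubFit(VARIANTS[0], 10.0)]
        selected, _ = compare_variants(fits)
        assert selected == VARIANTS[0]

    def test_order_invariance(self):
        fits = [_StubFit(v, w) for v, w in zip(VARIANTS, [3.0, 2.0, 1.0,
                                                          4.0])]
        a, _ = compare_variants(fits)
        b, _ = compare_variants(fits[::-1])
        assert a == b == VARIANTS[2]


class TestRefit:
    def test_converged_fit_is_passthrough(self, fitted):
        _, res = fitted
        converged = ADMResults(model=res.model, config=res.config,
                               samples=res.samples, log_prob=res.log_prob,
                               rhat={k: 1.0 for k in res.rhat})
        assert refit_with_informed_inits(converged) is converged

    def test_informed_inits_within_best_chain_hdi(self, fitted):
        _, res = fitted
        # force "best chain = 1" by doctoring log_prob
        lp = res.log_prob.copy()
        lp[1] += 1000.0
        doctored = ADMResults(model=res.model, config=res.config,
                              samples=res.samples, log_prob=lp,
                              rhat={k: 2.0 for k in res.rhat})
        rng = np.random.default_rng(0)
        inits = informed_inits(doctored, 10, rng)
        for k, name in enumerate(res.param_names):
            lo, hi = hdi(res.samples[name][1])
            assert np.all(inits[:, k] >= lo) and np.all(inits[:, k] <= hi)

    def test_refit_runs_and_counts(self, fitted):
        _, res = fitted
        doctored = ADMResults(model=res.model, config=res.config,
                              samples=res.samples, log_prob=res.log_prob,
                              rhat={k: 2.0 for k in res.rhat})
        out = refit_with_informed_inits(doctored, TINY, strict=False)
        assert out.n_refits == 1
        assert out is not doctored
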