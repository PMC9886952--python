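"""Learning-curve model, variants, derived effects."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import dislearn as dl
from dislearn import bayes_core as bc
from dislearn import learning_curves as lc
from dislearn import preprocessing as pp
from dislearn.synthetic_data import DesignConfig, GeneratingParams


class TestLcMean:
    @pytest.mark.parametrize(
        "s, a, c, x, expected",
        [
            (800.0, 600.0, 0.7, 0, 800.0),   # value at block 0 is s
            (700.0, 700.0, 1.3, 5, 700.0),   # degenerate flat curve
            (800.0, 600.0, 1.0, 3, 650.0),   # 600 + 200 / 4
        ],
    )
    def test_worked_values(self, s, a, c, x, expected):
        assert float(lc.lc_mean(s, a, c, x)) == pytest.approx(expected)

    def test_monotone_between_s_and_a(self):
        x = np.arange(0, 20)
        y = lc.lc_mean(800.0, 600.0, 0.8, x)
        assert np.all(np.diff(y) < 0)
        assert np.all((y <= 800.0) & (y >= 600.0))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            lc.lc_mean(800, 600, 0.0, 1)
        with pytest.raises(ValueError):
            lc.lc_mean(800, 600, 1.0, -1)


class TestVariants:
    def test_parameter_count_nesting(self):
        counts = {v: lc.build_variant(v).n_participant_params
                  for v in lc.VARIANTS}
        assert counts["none"] < counts["asymptote_only"] <= counts["both"]
        assert counts["none"] < counts["rate_only"] <= counts["both"]

    def test_asymptote_only_single_rate_slot(self):
        spec = lc.build_variant("asymptote_only")
        assert spec.n_c == 1
        assert spec.n_a == 3

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            lc.build_variant("everything")

    def test_both_with_zero_effects_reproduces_none_likelihood(
            self, clean_trials):
        cells = lc.block_means(clean_trials)
        cells = cells.loc[cells["task"] == "fixed"]
        m_both = lc._LearningModel(cells, lc.build_variant("both"),
                                   lc.LearningPriors())
        m_none = lc._LearningModel(cells, lc.build_variant("none"),
                                   lc.LearningPriors())
        rng = np.random.default_rng(0)
        z = rng.normal(0, 0.5, (m_none.n_part, m_none.P))
        # craft equivalent draws: identical values in every condition slot
        th_none = np.zeros(m_none.ndim)
        th_none[m_none.i_mu_lev] = [750, 770, 640]
        th_none[m_none.i_lt_lev] = np.log([30, 30, 25])
        th_none[m_none.i_mu_logc] = np.log(0.8)
        th_none[m_none.i_lt_logc] = np.log(0.1)
        th_none[m_none.i_mu_logsd] = np.log(40)
        th_none[m_none.i_lt_logsd] = np.log(0.1)
        th_none[m_none.n_hyper:] = z.ravel()

        th_both = np.zeros(m_both.ndim)
        th_both[m_both.i_mu_lev] = [750, 770, 640, 640, 640]
        th_both[m_both.i_lt_lev] = np.log([30, 30, 25, 25, 25])
        th_both[m_both.i_mu_logc] = np.log(0.8)
        th_both[m_both.i_lt_logc] = np.log(0.1)
        th_both[m_both.i_mu_logsd] = np.log(40)
        th_both[m_both.i_lt_logsd] = np.log(0.1)
        zb = np.zeros((m_both.n_part, m_both.P))
        zb[:, 0:2] = z[:, 0:2]          # s offsets
        zb[:, 2:5] = z[:, [2]]          # same a offset in all three slots
        zb[:, 5:] = z[:, 3:]            # rate and sd offsets
        th_both[m_both.n_hyper:] = zb.ravel()

        ll_none = m_none.loglik_matrix(th_none[None, :])
        ll_both = m_both.loglik_matrix(th_both[None, :])
        assert np.allclose(ll_none, ll_both)


class TestFitLearning:
    def test_noise_free_recovery(self, noise_free_params):
        params = dataclasses.replace(noise_free_params, trial_sd=5.0)
        cfg = DesignConfig(tasks=("fixed",), n_participants_per_task=8)
        trials = dl.simulate_experiment(cfg, params, mode="condition", seed=5)
        clean, _ = pp.preprocess(trials, criterion="strict")
        cells = lc.block_means(clean)
        fit = lc.fit_learning(cells, variant="both",
                              config=bc.SamplerConfig(n_steps=400, n_burn=900,
                                                      max_leapfrog=32, seed=0))
        gen = params.curves["fixed"]
        tf = fit.task_fits["fixed"]
        flat = tf.samples.flat()
        for cond in lc.CONDITIONS:
            a_mode = bc.posterior_mode(
                tf.model.condition_param_draws(flat, "a", cond).mean(axis=1))
            assert a_mode == pytest.approx(gen.a(cond), rel=0.05)
            s_mode = bc.posterior_mode(
                tf.model.condition_param_draws(flat, "s", cond).mean(axis=1))
            assert s_mode == pytest.approx(gen.s(cond), rel=0.05)

    def test_too_few_participants_rejected(self, clean_trials):
        cells = lc.block_means(clean_trials)
        two = cells.loc[cells["participant_id"].isin(
            cells["participant_id"].unique()[:2])]
        with pytest.raises(ValueError, match="participants"):
            lc.fit_learning(two, variant="none")

    def test_shuffled_labels_null_effects(self):
        cfg = DesignConfig(tasks=("fixed",), n_participants_per_task=12)
        trials = dl.simulate_experiment(cfg, mode="condition", seed=21)
        clean, _ = pp.preprocess(trials, criterion="strict")
        rng = np.random.default_rng(3)
        clean = clean.copy()
        clean["condition"] = rng.permutation(clean["condition"].to_numpy())
        cells = lc.block_means(clean)
        fit = lc.fit_learning(cells, variant="both",
                              config=bc.SamplerConfig(n_steps=400, n_burn=900,
                                                      max_leapfrog=32, seed=0))
        eff = lc.derive_effects(fit).per_task["fixed"]
        for name in ("delta_a_low", "delta_a_high", "SE"):
            s = eff[name]
            assert s.hpd_low <= 0.0 <= s.hpd_high


class TestDeriveEffects:
    def _fabricated_fit(self, cells, mu_by_draw):
        """Build a LearningFit whose draws encode prescribed group values."""
        model = lc._LearningModel(cells, lc.build_variant("both"),
                                  lc.LearningPriors())
        n = len(mu_by_draw)
        flat = np.zeros((n, model.ndim))
        for i, mu in enumerate(mu_by_draw):
            flat[i, model.i_mu_lev] = [mu["s_absent"], mu["s_present"],
                                       mu["a_absent"], mu["a_high"],
                                       mu["a_low"]]
            flat[i, model.i_lt_lev] = -10.0  # tau -> 0: all participants equal
            flat[i, model.i_mu_logc] = np.log(0.8)
            flat[i, model.i_lt_logc] = -10.0
            flat[i, model.i_mu_logsd] = np.log(40)
            flat[i, model.i_lt_logsd] = -10.0
        samples = bc.PosteriorSamples(
            chain=flat[:, None, :], names=model.names,
            rhat=np.ones(model.ndim), acceptance_rate=1.0)
        tf = lc.LearningTaskFit(task="fixed", variant="both", model=model,
                                samples=samples)
        return lc.LearningFit(variant="both", task_fits={"fixed": tf})

    def test_constant_draws_arithmetic(self, clean_trials):
        cells = lc.block_means(clean_trials)
        cells = cells.loc[cells["task"] == "fixed"]
        mu = {"s_absent": 720, "s_present": 760, "a_absent": 600,
              "a_high": 612, "a_low": 640}
        fit = self._fabricated_fit(cells, [mu] * 5)
        eff = lc.derive_effects(fit).per_task["fixed"]
        assert eff["DI"].mode == pytest.approx(40.0)
        assert eff["DI"].hpd_low == pytest.approx(40.0)
        assert eff["DI"].hpd_high == pytest.approx(40.0)
        assert eff["SE"].mode == pytest.approx(28.0)

    def test_se_computed_draw_wise_not_from_summaries(self, clean_trials):
        # a mixture where mode(SE draws) differs from the difference of the
        # component modes
        cells = lc.block_means(clean_trials)
        cells = cells.loc[cells["task"] == "fixed"]
        base = {"s_absent": 720, "s_present": 760, "a_absent": 600}
        draws = []
        for _ in range(60):      # 60%: Delta-a (40, 30)
            draws.append({**base, "a_high": 630, "a_low": 640})
        for _ in range(40):      # 40%: Delta-a (10, 0)
            draws.append({**base, "a_high": 600, "a_low": 610})
        fit = self._fabricated_fit(cells, draws)
        eff = lc.derive_effects(fit).per_task["fixed"]
        # SE draws are exactly the elementwise difference of the Delta-a
        # draws (the mixture makes this differ from any summary-first
        # computation: the SE draws are constant 10)
        np.testing.assert_allclose(
            eff["SE"].samples_ref,
            eff["delta_a_low"].samples_ref - eff["delta_a_high"].samples_ref)
        assert eff["SE"].mode == pytest.approx(10.0, abs=0.5)
        assert eff["SE"].hpd_low == pytest.approx(10.0)
        assert eff["SE"].hpd_high == pytest.approx(10.0)


class TestPosteriorPredictive:
    def test_coverage_of_block_means(self):
        cfg = DesignConfig(tasks=("fixed",), n_participants_per_task=10)
        trials = dl.simulate_experiment(cfg, mode="condition", seed=9)
        clean, _ = pp.preprocess(trials, criterion="strict")
        cells = lc.block_means(clean)
        fit = lc.fit_learning(cells, variant="both",
                              config=bc.SamplerConfig(n_steps=400, n_burn=900,
                                                      max_leapfrog=32, seed=1))
        pred = lc.posterior_predictive(fit, include_noise=True)
        merged = cells.merge(pred, left_on=["task", "participant_id",
                                            "condition", "x"],
                             right_on=["task", "participant_id",
                                       "condition", "x"])
        inside = ((merged["mean_rt"] >= merged["lo"])
                  & (merged["mean_rt"] <= merged["hi"])).mean()
        assert 0.90 <= inside <= 1.0
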