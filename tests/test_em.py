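"""EM estimation: likelihood, expected counts, closed-form M-steps, recovery."""

import numpy as np
import pytest

from cdmtau import (
    ItemParamsDINA,
    ItemParamsGDINA,
    LatentDist,
    QMatrix,
    SimCondition,
    fit_em,
    gen_responses,
    marginal_loglik,
    simulate_dataset,
)
from cdmtau.em import e_step, m_step_dina, m_step_gdina

from conftest import oracle_marginal_loglik
from test_model_core import random_instance


class TestMarginalLoglik:
    def test_two_term_sum(self):
        q = QMatrix([[1]])
        params = ItemParamsDINA([0.2], [0.2])
        pi = LatentDist([0.5, 0.5])
        ll = marginal_loglik(np.array([[1]]), params, pi, q)
        assert ll == pytest.approx(np.log(0.8 * 0.5 + 0.2 * 0.5))

    def test_additive_over_persons(self, rng):
        q, params, pi, x = random_instance(rng, K=3, J=5)
        single = marginal_loglik(x, params, pi, q)
        doubled = marginal_loglik(np.vstack([x, x]), params, pi, q)
        assert doubled == pytest.approx(2 * single, rel=1e-12)

    @pytest.mark.parametrize("model", ["dina", "gdina"])
    def test_matches_enumeration_oracle(self, rng, model):
        q, params, pi, x = random_instance(rng, K=3, J=6, model=model)
        got = marginal_loglik(x, params, pi, q)
        expected = oracle_marginal_loglik(x, params, pi.pi, q.entries, K=3)
        assert got == pytest.approx(expected, abs=1e-10)


class TestEStep:
    def test_point_mass_prior_concentrates_counts(self):
        q = QMatrix([[1]])
        params = ItemParamsDINA([0.2], [0.2])
        pi = LatentDist([0.0, 1.0])
        _, class_mass, correct = e_step(np.array([[1], [0], [1]]), params, pi, q)
        np.testing.assert_allclose(class_mass, [0.0, 3.0])
        np.testing.assert_allclose(correct[:, 0], [0.0, 2.0])

    def test_class_mass_sums_to_n(self, rng):
        q, params, pi, x = random_instance(rng, K=3, J=5)
        _, class_mass, _ = e_step(x, params, pi, q)
        assert class_mass.sum() == pytest.approx(len(x), abs=1e-10)

    def test_counts_match_monte_carlo_imputation(self, rng):
        """Expected counts equal the average of sampled class memberships."""
        q, params, pi, x = random_instance(rng, K=2, J=4)
        post, class_mass, correct = e_step(x, params, pi, q)
        draws = 200_000
        tally = np.zeros_like(class_mass)
        hits = np.zeros_like(correct)
        for i in range(len(x)):
            classes = rng.choice(post.shape[1], size=draws, p=post[i])
            counts = np.bincount(classes, minlength=post.shape[1]) / draws
            tally += counts
            hits += counts[:, None] * x[i]
        se = 3 * np.sqrt(len(x) * 0.25 / draws)
        np.testing.assert_allclose(tally, class_mass, atol=se)
        np.testing.assert_allclose(hits, correct, atol=se)


class TestMSteps:
    def test_dina_closed_form_proportion(self):
        # one single-attribute item; all mass on non-masters, half correct
        q = QMatrix([[1]])
        class_mass = np.array([4.0, 0.0])
        correct = np.array([[2.0], [0.0]])
        prev = ItemParamsDINA([0.5], [0.5])
        updated = m_step_dina(class_mass, correct, q, prev)
        assert updated.guess[0] == pytest.approx(0.5)
        assert updated.slip[0] == pytest.approx(0.5)  # zero master mass: kept

    def test_gdina_closed_form_proportion(self):
        q = QMatrix([[1]])
        class_mass = np.array([0.0, 100.0])
        correct = np.array([[0.0], [73.0]])
        prev = ItemParamsGDINA([np.array([0.3, 0.5])])
        updated = m_step_gdina(class_mass, correct, q, prev)
        assert updated.tables[0][1] == pytest.approx(0.73)
        assert updated.tables[0][0] == pytest.approx(0.3)  # zero-mass group kept

    @pytest.mark.parametrize("model", ["dina", "gdina"])
    def test_fixed_point_at_truth(self, model, q15):
        """One EM step from the generating parameters barely moves at N=20000:
        each update stays within 4 binomial standard errors of its group."""
        x, _, params, q = simulate_dataset(
            SimCondition(model=model, J=15, N=20000, iq=0.6), seed=5
        )
        pi = LatentDist.uniform(q.K)  # generating attribute structure is uniform
        _, class_mass, correct = e_step(x, params, pi, q)
        step = m_step_dina if model == "dina" else m_step_gdina
        updated = step(class_mass, correct, q, params)
        delta = np.abs(updated.flat() - params.flat())
        assert delta.mean() < 0.01
        # per-parameter: within sampling noise of the smallest latent group
        min_mass = min(
            np.bincount(q.reduced_index[j], weights=class_mass).min()
            for j in range(q.J)
        )
        assert delta.max() < 4 * np.sqrt(0.25 / min_mass)


class TestFitEM:
    def test_dina_parameter_recovery(self, q15):
        params = ItemParamsDINA(np.full(15, 0.1), np.full(15, 0.1))
        rng = np.random.default_rng(17)
        alpha = (rng.random((5000, 5)) < 0.5).astype(int)
        x = gen_responses(alpha, params, q15, seed=18)
        fit = fit_em(x, q15, "dina")
        err = np.abs(fit.params.flat() - params.flat())
        assert err.max() < 0.03
        assert err.mean() < 0.02
        assert fit.converged

    @pytest.mark.parametrize("model", ["dina", "gdina"])
    def test_loglik_nondecreasing(self, model, q15):
        x, _, _, q = simulate_dataset(
            SimCondition(model=model, J=15, N=150, iq=0.4), seed=6
        )
        fit = fit_em(x, q, model)
        assert np.all(np.diff(fit.loglik_path) >= -1e-8)

    def test_pi_is_a_distribution(self, q15):
        x, _, _, _ = simulate_dataset(SimCondition(N=120, iq=0.4), seed=7)
        fit = fit_em(x, q15, "dina")
        assert (fit.pi.pi >= 0).all()
        assert fit.pi.pi.sum() == pytest.approx(1.0, abs=1e-10)

    def test_constant_column_clamps_and_completes(self, q15):
        x, _, _, _ = simulate_dataset(SimCondition(N=80, iq=0.8), seed=8)
        x = x.copy()
        x[:, 0] = 1  # item answered correctly by everyone
        fit = fit_em(x, q15, "dina")
        assert fit.params.guess[0] >= 1 - 1e-3
        assert fit.params.slip[0] <= 1e-3
        assert np.isfinite(fit.loglik)

    def test_recovery_improves_with_n(self, q15):
        """Mean absolute parameter error shrinks from N=200 to N=5000."""
        errs = {200: [], 5000: []}
        for seed in range(10):
            for n in errs:
                cond = SimCondition(model="dina", J=15, N=n, iq=0.6)
                x, _, params, q = simulate_dataset(cond, seed=100 + seed)
                fit = fit_em(x, q, "dina")
                errs[n].append(np.abs(fit.params.flat() - params.flat()).mean())
        assert np.mean(errs[5000]) < np.mean(errs[200])

    def test_gdina_recovers_dina_pattern(self, q15):
        """Fitting the saturated model on conjunctive data at large N gives
        near-equal probabilities across the non-full-mastery reduced classes."""
        x, _, _, q = simulate_dataset(
            SimCondition(model="dina", J=15, N=20000, iq=0.8), seed=9
        )
        fit = fit_em(x, q, "gdina")
        for j in range(q.J):
            non_master = fit.params.tables[j][:-1]
            if non_master.size > 1:
                assert non_master.max() - non_master.min() < 0.05

    def test_dimension_mismatch_raises(self, q15):
        with pytest.raises(ValueError):
            fit_em(np.zeros((10, 7)), q15, "dina")
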