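"""TSK inference layers and hybrid LSE/gradient training."""

import json

import numpy as np
import pytest

from dsanfis.anfis import (AnfisConfig, AnfisModel, membership_degree,
                           normalize_firing, predict_class)
from dsanfis.rules import FuzzyRule, GaussianMF, RuleBase


def two_rule_model(convention="half", consequents=(0.0, 1.0)):
    rb = RuleBase(rules=[
        FuzzyRule([GaussianMF(0.3, 0.1), GaussianMF(0.6, 0.2)], consequents[0]),
        FuzzyRule([GaussianMF(0.7, 0.15), GaussianMF(0.2, 0.1)], consequents[1]),
    ], feature_names=["a", "b"])
    return AnfisModel(rb, AnfisConfig(mf_convention=convention))


class TestMembership:
    def test_peak_at_center(self):
        assert membership_degree(GaussianMF(0.4, 0.1), 0.4) == 1.0

    def test_half_convention_hand_value(self):
        # c=0.96, sigma=0.04, x=0.88: (0.08)^2 / (2*0.04^2) = 2
        mu = membership_degree(GaussianMF(0.96, 0.04), 0.88)
        assert mu == pytest.approx(np.exp(-2), abs=1e-12)

    def test_plain_convention_hand_value(self):
        mu = membership_degree(GaussianMF(0.96, 0.04), 0.88, convention="plain")
        assert mu == pytest.approx(np.exp(-4), abs=1e-12)

    def test_symmetric_about_center(self):
        mf = GaussianMF(0.5, 0.12)
        for d in (0.05, 0.2, 0.4):
            assert membership_degree(mf, 0.5 + d) == pytest.approx(
                membership_degree(mf, 0.5 - d))


class TestFiring:
    def test_input_at_rule_center_fires_fully(self):
        m = two_rule_model()
        w = m.firing_strengths([[0.3, 0.6]])
        assert w[0, 0] == pytest.approx(1.0)

    def test_product_t_norm(self):
        rb = RuleBase(rules=[FuzzyRule(
            [GaussianMF(0.0, 1.0), GaussianMF(0.0, 1.0)], 1.0)],
            feature_names=["a", "b"])
        m = AnfisModel(rb)
        x = [np.sqrt(2 * np.log(2)), np.sqrt(2 * np.log(5))]  # mu = 0.5, 0.2
        assert m.firing_strengths([x])[0, 0] == pytest.approx(0.1)

    def test_matches_naive_loop_oracle(self, rng):
        m = two_rule_model()
        X = rng.uniform(size=(10, 2))
        w = m.firing_strengths(X)
        for i in range(10):
            for d in range(2):
                expect = 1.0
                for k in range(2):
                    expect *= membership_degree(
                        GaussianMF(m.centers[d, k], m.sigmas[d, k]), X[i, k])
                assert w[i, d] == pytest.approx(expect, abs=1e-12)

    def test_missing_feature_rejected(self):
        with pytest.raises(ValueError, match="impute"):
            two_rule_model().firing_strengths([[0.1, np.nan]])


class TestNormalization:
    def test_single_rule_normalizes_to_one(self):
        wbar, flag = normalize_firing(np.array([0.42]))
        assert wbar.tolist() == [1.0] and not flag

    def test_proportional_split(self):
        wbar, _ = normalize_firing(np.array([0.3, 0.1]))
        np.testing.assert_allclose(wbar, [0.75, 0.25])

    def test_always_sums_to_one(self, rng):
        w = rng.uniform(size=(20, 5))
        wbar, _ = normalize_firing(w)
        np.testing.assert_allclose(wbar.sum(axis=1), 1.0, atol=1e-12)

    def test_underflow_falls_back_to_uniform_flagged(self):
        wbar, flag = normalize_firing(np.array([0.0, 0.0, 0.0]))
        np.testing.assert_allclose(wbar, 1 / 3)
        assert flag


class TestInference:
    def test_equal_consequents_constant_output(self, rng):
        m = two_rule_model(consequents=(0.7, 0.7))
        np.testing.assert_allclose(m.infer(rng.uniform(size=(15, 2))), 0.7,
                                   atol=1e-12)

    def test_output_within_consequent_range(self, rng):
        m = two_rule_model(consequents=(-0.2, 1.3))
        z = m.infer(rng.uniform(-1, 2, size=(50, 2)))
        assert np.all(z >= -0.2 - 1e-12) and np.all(z <= 1.3 + 1e-12)

    def test_two_rule_hand_computation(self):
        m = two_rule_model(consequents=(0.0, 1.0))
        x = np.array([0.5, 0.5])
        w1 = np.exp(-(0.2 ** 2) / (2 * 0.01)) * np.exp(-(0.1 ** 2) / (2 * 0.04))
        w2 = np.exp(-(0.2 ** 2) / (2 * 0.0225)) * np.exp(-(0.3 ** 2) / (2 * 0.01))
        expect = (w1 * 0.0 + w2 * 1.0) / (w1 + w2)
        assert m.infer([x])[0] == pytest.approx(expect, abs=1e-12)


class TestPredictClass:
    @pytest.mark.parametrize("z,cls,conf", [
        (0.776, 1, 0.776),   # positive diagnosis at 77.6% confidence
        (0.5, 1, 0.5),       # boundary ties to positive
        (0.2, 0, 0.8),
    ])
    def test_threshold_and_confidence(self, z, cls, conf):
        got_cls, got_conf = predict_class(z)
        assert got_cls == cls and got_conf == pytest.approx(conf)


class TestLeastSquaresConsequents:
    def test_single_rule_gets_label_mean(self, rng):
        rb = RuleBase(rules=[FuzzyRule([GaussianMF(0.5, 0.2)], 0.0)],
                      feature_names=["a"])
        m = AnfisModel(rb)
        y = np.array([0.0, 1.0, 1.0, 1.0])
        m.lse_consequents(rng.uniform(size=(4, 1)), y)
        assert m.consequents[0] == pytest.approx(y.mean())

    def test_matches_normal_equations_oracle(self, rng):
        m = two_rule_model()
        X = rng.uniform(size=(4, 2))
        y = rng.uniform(size=4)
        wbar, _ = normalize_firing(m.firing_strengths(X))
        oracle = np.linalg.solve(wbar.T @ wbar, wbar.T @ y)
        m.lse_consequents(X, y)
        np.testing.assert_allclose(m.consequents, oracle, atol=1e-8)

    def test_sse_never_increases(self, rng):
        m = two_rule_model()
        X = rng.uniform(size=(30, 2))
        y = rng.integers(0, 2, 30).astype(float)
        before = m.mse(X, y)
        m.lse_consequents(X, y)
        assert m.mse(X, y) <= before + 1e-12

    def test_identically_firing_rules_minimum_norm(self):
        # duplicate rules make the design matrix rank-deficient
        rb = RuleBase(rules=[
            FuzzyRule([GaussianMF(0.5, 0.1)], 0.0),
            FuzzyRule([GaussianMF(0.5, 0.1)], 1.0)],
            feature_names=["a"])
        m = AnfisModel(rb)
        X = np.array([[0.4], [0.5], [0.6]])
        y = np.array([1.0, 1.0, 0.0])
        m.lse_consequents(X, y)
        assert np.all(np.isfinite(m.consequents))
        assert m.consequents[0] == pytest.approx(m.consequents[1])


class TestPremiseGradient:
    def test_zero_training_error_is_stationary(self):
        m = two_rule_model(consequents=(0.5, 0.5))
        X = np.array([[0.1, 0.2], [0.8, 0.9]])
        y = np.array([0.5, 0.5])      # exact fit: zero gradient
        c0, s0 = m.centers.copy(), m.sigmas.copy()
        m.gradient_premise_step(X, y)
        np.testing.assert_allclose(m.centers, c0, atol=1e-14)
        np.testing.assert_allclose(m.sigmas, s0, atol=1e-14)

    @pytest.mark.parametrize("convention", ["half", "plain"])
    def test_analytic_gradient_matches_central_differences(self, convention, rng):
        m = two_rule_model(convention=convention)
        X = rng.uniform(size=(12, 2))
        y = rng.integers(0, 2, 12).astype(float)
        c0, s0 = m.centers.copy(), m.sigmas.copy()
        lr = 1e-3
        m.gradient_premise_step(X, y, learning_rate=lr)
        grad_c = (c0 - m.centers) / lr
        grad_s = (s0 - m.sigmas) / lr
        m.centers, m.sigmas = c0, s0

        h = 1e-6
        for d in range(2):
            for k in range(2):
                for arr, grad in ((m.centers, grad_c), (m.sigmas, grad_s)):
                    orig = arr[d, k]
                    arr[d, k] = orig + h
                    fp = m.mse(X, y)
                    arr[d, k] = orig - h
                    fm = m.mse(X, y)
                    arr[d, k] = orig
                    assert grad[d, k] == pytest.approx((fp - fm) / (2 * h),
                                                       abs=1e-5)

    def test_sigma_never_drops_below_floor(self, rng):
        m = two_rule_model()
        m.sigmas[:] = m.config.sigma_floor * 1.001
        X = rng.uniform(size=(20, 2))
        y = rng.integers(0, 2, 20).astype(float)
        for _ in range(5):
            m.gradient_premise_step(X, y, learning_rate=1.0)
            assert np.all(m.sigmas >= m.config.sigma_floor)


class TestFit:
    def test_zero_epochs_is_identity(self, rng):
        m = two_rule_model()
        state = (m.centers.copy(), m.sigmas.copy(), m.consequents.copy())
        m.fit(rng.uniform(size=(10, 2)), rng.integers(0, 2, 10), epochs=0)
        np.testing.assert_array_equal(m.centers, state[0])
        np.testing.assert_array_equal(m.sigmas, state[1])
        np.testing.assert_array_equal(m.consequents, state[2])
        assert m.history == []

    def test_training_improves_accuracy_on_two_blobs(self, rng):
        X = np.vstack([rng.normal(0.25, 0.08, (30, 2)),
                       rng.normal(0.75, 0.08, (30, 2))])
        y = np.repeat([0, 1], 30)
        # deliberately mis-centred initial rules
        rb = RuleBase(rules=[
            FuzzyRule([GaussianMF(0.4, 0.2), GaussianMF(0.4, 0.2)], 0.0),
            FuzzyRule([GaussianMF(0.6, 0.2), GaussianMF(0.6, 0.2)], 1.0)],
            feature_names=["a", "b"])
        m = AnfisModel(rb, AnfisConfig(epochs=30, learning_rate=0.1))
        before = np.mean(m.predict(X)[0] == y)
        m.fit(X, y)
        after = np.mean(m.predict(X)[0] == y)
        assert after >= before
        assert after >= 0.9

    def test_structure_invariant_under_training(self, rng):
        m = two_rule_model()
        m.fit(rng.uniform(size=(10, 2)), rng.integers(0, 2, 10), epochs=5)
        assert m.n_rules == 2 and m.n_features == 2
        assert len(m.history) == 5

    def test_mse_after_lse_step_not_worse(self, rng):
        m = two_rule_model()
        X = rng.uniform(size=(25, 2))
        y = rng.integers(0, 2, 25).astype(float)
        for _ in range(5):
            before = m.mse(X, y)
            m.lse_consequents(X, y)
            assert m.mse(X, y) <= before + 1e-12
            m.gradient_premise_step(X, y)


class TestRecovery:
    def test_generative_two_rule_centers_recovered(self, rng):
        """Data from a known 2-rule model: learned centers land within 0.1
        of the true ones after clustering init + hybrid fit."""
        from dsanfis import DominantSetAnfis, PipelineConfig

        true_centers = np.array([[0.2, 0.3], [0.8, 0.7]])
        X = np.vstack([rng.normal(true_centers[0], 0.05, (40, 2)),
                       rng.normal(true_centers[1], 0.05, (40, 2))])
        y = np.repeat([0, 1], 40)
        res = DominantSetAnfis(y, X, config=PipelineConfig(epochs=20)).fit()
        learned = res.engine.centers
        # compare in the normalized units the model learns in
        stats = [res.preprocessor[name] for name in res.model.feature_names]
        lo = np.array([s["min"] for s in stats])
        hi = np.array([s["max"] for s in stats])
        for tc in (true_centers - lo) / (hi - lo):
            d = np.linalg.norm(learned - tc, axis=1).min()
            assert d < 0.1


def test_model_json_roundtrip(rng):
    m = two_rule_model()
    m.fit(rng.uniform(size=(10, 2)), rng.integers(0, 2, 10), epochs=3)
    m2 = AnfisModel.from_json(m.to_json())
    assert m.to_json() == m2.to_json()
    X = rng.uniform(size=(5, 2))
    np.testing.assert_allclose(m.infer(X), m2.infer(X), atol=1e-12)
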