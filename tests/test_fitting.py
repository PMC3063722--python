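"""Moment matching, likelihood duality, and the brute-force entropy oracle."""

import numpy as np
import pytest

from mnemodels import (
    FitOptions,
    InfeasibleMomentsError,
    MomentVector,
    build_feature_map,
    empirical_moments,
    enumerate_gates,
    fit_mne,
    gate_dataset,
    gate_from_outputs,
    maxent_oracle,
    model_moments,
    named_gate,
)
from mnemodels.fitting import _neg_avg_loglik_and_grad

from conftest import GATE_OPTS


class TestEmpiricalMoments:
    def test_xor_first_order(self, xor_data):
        fm = build_feature_map(2, 1, binary_inputs=True)
        mv = empirical_moments(xor_data, fm)
        # XOR spikes on 01 and 10: rate 1/2, <y x_i> = 1/4 each
        np.testing.assert_allclose(mv.values, [0.5, 0.25, 0.25])

    def test_and_first_order(self, and_data):
        fm = build_feature_map(2, 1, binary_inputs=True)
        mv = empirical_moments(and_data, fm)
        np.testing.assert_allclose(mv.values, [0.25, 0.25, 0.25])

    def test_all_silent_gives_zero_moments(self):
        gate = gate_from_outputs([0, 0, 0, 0], 2)
        fm = build_feature_map(2, 2, binary_inputs=True)
        mv = empirical_moments(gate_dataset(gate), fm)
        np.testing.assert_allclose(mv.values, 0.0)


class TestFitMNE:
    def test_xor_first_order_is_the_uniform_model(self, xor_data):
        """The uniform-1/2 model satisfies all three first-order XOR
        constraints, so the fit must return it (no first-order structure)."""
        fm = build_feature_map(2, 1, binary_inputs=True)
        fit = fit_mne(xor_data, fm, GATE_OPTS)
        assert fit.converged
        p = fit.model.predict(xor_data.ensemble.inputs)
        np.testing.assert_allclose(p, 0.5, atol=1e-6)

    def test_and_first_order_approaches_truth_table(self, and_data):
        """Three first-order constraints force the deterministic AND table
        as regularization vanishes."""
        fm = build_feature_map(2, 1, binary_inputs=True)
        fit = fit_mne(and_data, fm, FitOptions(l2_penalty=0.0, coefficient_cap=500.0))
        p = fit.model.predict(and_data.ensemble.inputs)
        truth = and_data.responses
        np.testing.assert_allclose(p, truth, atol=1e-4)

    def test_xor_second_order_predicts_near_zero_at_11(self, xor_data):
        fm = build_feature_map(2, 2, binary_inputs=True)
        fit = fit_mne(xor_data, fm, GATE_OPTS)
        assert fit.model.predict(np.array([1.0, 1.0])) < 1e-3

    def test_converged_fit_matches_moments(self, and_data):
        fm = build_feature_map(2, 2, binary_inputs=True)
        fit = fit_mne(and_data, fm, GATE_OPTS)
        assert fit.converged
        emp = empirical_moments(and_data, fm).values
        mod = model_moments(fit.model, and_data.ensemble).values
        assert np.max(np.abs(emp - mod)) <= GATE_OPTS.tolerance

    def test_degenerate_all_silent_returns_constant_model_with_warning(self):
        gate = gate_from_outputs([0, 0, 0, 0], 2)
        data = gate_dataset(gate)
        fm = build_feature_map(2, 1, binary_inputs=True)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            fit = fit_mne(data, fm, GATE_OPTS)
        assert np.all(fit.model.predict(data.ensemble.inputs) < 1e-6)

    def test_determinism_bit_for_bit(self, and_data):
        fm = build_feature_map(2, 2, binary_inputs=True)
        c1 = fit_mne(and_data, fm, GATE_OPTS).model.coefficients
        c2 = fit_mne(and_data, fm, GATE_OPTS).model.coefficients
        assert c1 == c2

    def test_likelihood_gradient_equals_moment_mismatch(self, and_data):
        """The duality behind the method: at any coefficient vector, the
        gradient of the negative average log-likelihood equals the
        empirical-minus-model moment mismatch."""
        fm = build_feature_map(2, 2, binary_inputs=True)
        F = fm.design_matrix(and_data.ensemble.inputs)
        y, w = and_data.responses, and_data.ensemble.weights
        rng = np.random.default_rng(0)
        for _ in range(5):
            coef = rng.normal(scale=2.0, size=fm.n_features)
            _, grad = _neg_avg_loglik_and_grad(coef, F, y, w, 0.0)
            from mnemodels import MNEModel

            emp = empirical_moments(and_data, fm).values
            mod = model_moments(MNEModel(fm, tuple(coef)), and_data.ensemble).values
            np.testing.assert_allclose(grad, emp - mod, atol=1e-12)

    def test_binary_encoding_redundancy(self):
        """For 0/1 inputs, adding the squared monomial cannot improve the
        achievable fit: x^2 = x merges into the linear coefficient."""
        data = gate_dataset(named_gate("OR"))
        fm_plain = build_feature_map(2, 1, binary_inputs=True)
        from mnemodels import FeatureMap

        fm_sq = FeatureMap(
            n_inputs=2, order=2,
            monomials=((), (0,), (1,), (0, 0), (1, 1)),
            binary_inputs=False,
        )
        f1 = fit_mne(data, fm_plain, GATE_OPTS)
        f2 = fit_mne(data, fm_sq, GATE_OPTS)
        p1 = f1.model.predict(data.ensemble.inputs)
        p2 = f2.model.predict(data.ensemble.inputs)
        np.testing.assert_allclose(p1, p2, atol=1e-5)


class TestMaxentOracle:
    def test_xor_first_order_oracle_is_uniform(self, xor_data):
        fm = build_feature_map(2, 1, binary_inputs=True)
        m = empirical_moments(xor_data, fm)
        q = maxent_oracle(m, xor_data.ensemble)
        np.testing.assert_allclose(q, 0.5, atol=1e-7)

    def test_xor_second_order_oracle_recovers_truth_table(self, xor_data):
        fm = build_feature_map(2, 2, binary_inputs=True)
        m = empirical_moments(xor_data, fm)
        q = maxent_oracle(m, xor_data.ensemble)
        np.testing.assert_allclose(q, xor_data.responses, atol=1e-7)

    def test_mean_only_constraint_gives_uniform_half(self, xor_data):
        fm = build_feature_map(2, 1, binary_inputs=True)
        from mnemodels import FeatureMap

        fm0 = FeatureMap(n_inputs=2, order=1, monomials=((),), binary_inputs=True)
        m = MomentVector(feature_map=fm0, values=np.array([0.5]))
        q = maxent_oracle(m, xor_data.ensemble)
        np.testing.assert_allclose(q, 0.5, atol=1e-8)

    def test_infeasible_moments_raise_identifying_constraint(self, xor_data):
        fm = build_feature_map(2, 1, binary_inputs=True)
        bad = MomentVector(feature_map=fm, values=np.array([0.1, 0.2, 0.2]))
        # <y x1> = 0.2 > <y> = 0.1 is impossible for 0/1 variables
        with pytest.raises(InfeasibleMomentsError, match=r"\(0,\)|\(1,\)"):
            maxent_oracle(bad, xor_data.ensemble)

    def test_state_guard(self):
        from mnemodels import InputEnsemble

        X = np.arange(5000.0)[:, None]
        ens = InputEnsemble.from_samples(X)
        fm = build_feature_map(1, 1)
        m = MomentVector(feature_map=fm, values=np.array([0.5, 0.0]))
        with pytest.raises(ValueError, match="guard"):
            maxent_oracle(m, ens)

    def test_oracle_equivalence_on_all_two_input_gates(self):
        """The logistic fit attains the constrained entropy maximum: its
        conditional table agrees with the direct oracle on every
        non-degenerate 2-input deterministic gate."""
        opts = FitOptions(l2_penalty=0.0, coefficient_cap=500.0)
        fm = build_feature_map(2, 2, binary_inputs=True)
        for gate in enumerate_gates(2):
            data = gate_dataset(gate)
            if data.mean_output in (0.0, 1.0):
                continue
            m = empirical_moments(data, fm)
            q = maxent_oracle(m, data.ensemble)
            p = fit_mne(data, fm, opts).model.predict(data.ensemble.inputs)
            assert np.max(np.abs(q - p)) < 1e-6

    def test_oracle_equivalence_on_stochastic_table(self):
        gate = gate_from_outputs([0.1, 0.7, 0.4, 0.9], 2)
        data = gate_dataset(gate)
        fm = build_feature_map(2, 2, binary_inputs=True)
        m = empirical_moments(data, fm)
        q = maxent_oracle(m, data.ensemble)
        p = fit_mne(data, fm, FitOptions(l2_penalty=0.0, coefficient_cap=500.0)).model.predict(
            data.ensemble.inputs
        )
        assert np.max(np.abs(q - p)) < 1e-6

    def test_feasible_perturbations_never_increase_entropy(self):
        """Noise-entropy maximality: moving the fitted table along the
        null space of the constraints (staying feasible) can only lower
        the ensemble-averaged binary entropy."""
        from mnemodels import binary_entropy

        gate = gate_from_outputs([0.2, 0.6, 0.5, 0.8], 2)
        data = gate_dataset(gate)
        fm = build_feature_map(2, 1, binary_inputs=True)
        m = empirical_moments(data, fm)
        fit = fit_mne(data, fm, FitOptions(l2_penalty=0.0, coefficient_cap=500.0))
        states = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        q = fit.model.predict(states)
        Pw = np.full(4, 0.25)
        A = (fm.design_matrix(states) * Pw[:, None]).T  # constraints: A @ q = m
        null = np.linalg.svd(A)[2][np.linalg.matrix_rank(A):]
        assert null.shape[0] >= 1
        h0 = Pw @ binary_entropy(q)
        rng = np.random.default_rng(1)
        for _ in range(50):
            d = null.T @ rng.normal(size=null.shape[0])
            for eps in (1e-3, 1e-2, 5e-2):
                q2 = q + eps * d
                if np.any(q2 <= 0) or np.any(q2 >= 1):
                    continue
                assert Pw @ binary_entropy(q2) <= h0 + 1e-9
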