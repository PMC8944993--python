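"""Forward pass, Jacobian, Levenberg-Marquardt trainer, architecture search."""

import math

import numpy as np
import pytest

from sgann import (CohortConfig, NetworkParams, TrainingConfig,
                   architecture_search, forward, generate_oracle_cohort,
                   jacobian, logsig, rmse, tansig, train_lm)
from sgann.network import init_params
from conftest import random_network


def scalar_forward(x, p):
    """Independent scalar-loop implementation of the forward pass."""
    out_acc = p.b2
    for j in range(p.h):
        z = p.b1[j]
        for i in range(p.n_inputs):
            z += p.Wi[j, i] * x[i]
        a = math.tanh(z)
        out_acc += p.Wo[j] * a
    return 1.0 / (1.0 + math.exp(-out_acc))


def fd_jacobian(p, X, step=1e-6):
    """Central finite-difference Jacobian of the outputs w.r.t. parameters."""
    theta = p.to_vector()
    J = np.empty((len(X), theta.size))
    for k in range(theta.size):
        up, dn = theta.copy(), theta.copy()
        up[k] += step
        dn[k] -= step
        y_up = forward(X, NetworkParams.from_vector(up, p.h, p.n_inputs))
        y_dn = forward(X, NetworkParams.from_vector(dn, p.h, p.n_inputs))
        J[:, k] = (np.atleast_1d(y_up) - np.atleast_1d(y_dn)) / (2 * step)
    return J


class TestForward:
    def test_zero_network_outputs_half(self):
        p = NetworkParams(np.zeros((3, 14)), np.zeros(3), np.zeros(3), 0.0)
        x = np.linspace(0.1, 0.9, 14)
        assert forward(x, p) == 0.5
        batch = np.tile(x, (5, 1))
        np.testing.assert_array_equal(forward(batch, p), np.full(5, 0.5))

    def test_saturation_toward_one(self):
        # large positive output weight on a positively-activated hidden unit
        p = NetworkParams(np.ones((1, 14)), [0.0], [50.0], 0.0)
        assert forward(np.full(14, 0.5), p) > 0.9999

    def test_matches_scalar_loop_oracle(self, rng):
        for _ in range(20):
            p = random_network(rng)
            x = rng.uniform(0.1, 0.9, size=14)
            assert abs(forward(x, p) - scalar_forward(x, p)) <= 1e-12

    def test_outputs_bounded(self, rng):
        p = random_network(rng, scale=5.0)
        X = rng.uniform(0.1, 0.9, size=(50, 14))
        y = forward(X, p)
        assert np.all((y > 0) & (y < 1))
        z = rng.normal(size=100)
        assert np.all(np.abs(tansig(z)) < 1)

    def test_dimension_and_finiteness_errors(self, rng):
        p = random_network(rng, h=2)
        with pytest.raises(ValueError):
            forward(np.zeros(13), p)
        with pytest.raises(ValueError):
            forward(np.full(14, np.nan), p)
        with pytest.raises(ValueError):
            NetworkParams(np.full((2, 14), np.inf), np.zeros(2), np.zeros(2), 0.0)


class TestRmse:
    def test_identical_vectors_zero(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_unit_error(self):
        assert rmse([1.0, 1.0], [0.0, 0.0]) == 1.0

    def test_matches_loop_oracle(self, rng):
        a = rng.normal(size=31)
        b = rng.normal(size=31)
        expected = math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)) / 31)
        assert rmse(a, b) == pytest.approx(expected, rel=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            rmse([], [])


class TestJacobian:
    def test_agrees_with_finite_differences_100_instances(self, rng):
        worst = 0.0
        for _ in range(100):
            p = random_network(rng)
            X = rng.uniform(0.1, 0.9, size=(3, 14))
            J = jacobian(p, X)
            J_fd = fd_jacobian(p, X)
            rel = np.max(np.abs(J - J_fd) / np.maximum(np.abs(J_fd), 1.0))
            worst = max(worst, rel)
        assert worst <= 1e-5

    def test_zero_network_b2_derivative_is_quarter(self):
        p = NetworkParams(np.zeros((2, 14)), np.zeros(2), np.zeros(2), 0.0)
        X = np.random.default_rng(0).uniform(0.1, 0.9, size=(6, 14))
        J = jacobian(p, X)
        np.testing.assert_allclose(J[:, -1], 0.25)   # logsig'(0) = 1/4

    def test_column_count_is_parameter_count(self, rng):
        for h in (1, 2, 5):
            p = random_network(rng, h=h)
            J = jacobian(p, rng.uniform(0.1, 0.9, size=(4, 14)))
            assert J.shape[1] == 14 * h + 2 * h + 1 == p.n_params


class TestTrainLM:
    def test_constant_targets_reach_goal_fast(self, rng):
        X = rng.uniform(0.1, 0.9, size=(30, 14))
        t = np.full(30, 0.5)
        zero = NetworkParams(np.zeros((1, 14)), [0.0], [0.0], 0.0)
        params, hist = train_lm(X, t, h=1,
                                config=TrainingConfig(max_epochs=50, goal=1e-6),
                                init=zero)
        assert rmse(forward(X, params), t) <= 1e-6

    def test_accepted_steps_monotone_and_rejects_never_mutate(self, rng):
        cohort, truth, _, _ = generate_oracle_cohort(
            CohortConfig(n_sga=10, n_aga=40, seed=3, mode="oracle"),
            return_details=True)
        from sgann import FEATURE_NAMES, fit_normalizer, normalize
        X = normalize(cohort[FEATURE_NAMES],
                      fit_normalizer(cohort[FEATURE_NAMES]))
        t = cohort.target.to_numpy()
        params, hist = train_lm(X, t, h=2,
                                config=TrainingConfig(max_epochs=150, seed=1))
        errs = np.array(hist.train_rmse)
        assert np.all(np.diff(errs) < 0)     # strictly decreasing accepted steps
        assert hist.stop_reason in {"goal", "max_epochs", "mu_overflow",
                                    "validation"}

    def test_noiseless_oracle_recovery_low_rmse(self):
        cohort, truth, _, _ = generate_oracle_cohort(
            CohortConfig(n_sga=28, n_aga=126, seed=8, mode="oracle",
                         oracle_noise_sd=0.0),
            return_details=True)
        from sgann import FEATURE_NAMES, fit_normalizer, normalize
        from sgann.network import train_with_restarts
        X = normalize(cohort[FEATURE_NAMES],
                      fit_normalizer(cohort[FEATURE_NAMES]))
        t = cohort.target.to_numpy()
        params, hist, _ = train_with_restarts(
            X, t, h=2, restarts=10, seeds=list(range(10)),
            config=TrainingConfig(max_epochs=400))
        assert rmse(forward(X, params), t) <= 1e-3

    def test_invalid_h_errors(self, rng):
        X = rng.uniform(size=(10, 14))
        with pytest.raises(ValueError):
            train_lm(X, np.full(10, 0.5), h=0)

    def test_deterministic_given_seed(self, rng):
        X = rng.uniform(0.1, 0.9, size=(40, 14))
        t = rng.uniform(0.4, 1.0, size=40)
        cfg = TrainingConfig(max_epochs=30, seed=5)
        p1, _ = train_lm(X, t, h=2, config=cfg)
        p2, _ = train_lm(X, t, h=2, config=cfg)
        np.testing.assert_array_equal(p1.to_vector(), p2.to_vector())

    def test_purelin_hidden_option(self, rng):
        X = rng.uniform(0.1, 0.9, size=(25, 14))
        t = rng.uniform(0.4, 1.0, size=25)
        params, _ = train_lm(X, t, h=1,
                             config=TrainingConfig(max_epochs=30),
                             hidden_activation="purelin")
        assert params.hidden_activation == "purelin"
        y = forward(X, params)
        assert np.all((y > 0) & (y < 1))

    def test_init_schemes(self):
        p_u = init_params(3, seed=1, scheme="uniform")
        assert np.all(np.abs(p_u.to_vector()) <= 0.5)
        p_nw = init_params(3, seed=1, scheme="nguyen-widrow")
        assert p_nw.h == 3
        with pytest.raises(ValueError):
            init_params(2, seed=0, scheme="xavier")


class TestArchitectureSearch:
    def test_recovers_oracle_scale_model(self):
        """Searching h = 1..4 on data from an h=2 truth selects a size able
        to represent it and fits the validation rows tightly."""
        from sgann import (FEATURE_NAMES, fit_normalizer, normalize,
                           regression_performance, split_dataset)
        cohort = generate_oracle_cohort(
            CohortConfig(n_sga=28, n_aga=126, seed=12, mode="oracle",
                         oracle_noise_sd=0.0))
        assign = split_dataset(cohort, (0.70, 0.15, 0.15), seed=2)
        X = normalize(cohort[FEATURE_NAMES],
                      fit_normalizer(cohort[FEATURE_NAMES]))
        t = cohort.target.to_numpy()
        tr = assign.indices("train")
        va = assign.indices("validation")
        params, hist, val_rmse, h_sel = architecture_search(
            X[tr], t[tr], X[va], t[va], max_hidden=4, restarts=20,
            config=TrainingConfig(max_epochs=200), seed=0)
        assert h_sel in {2, 3, 4}
        _, r2, _, _ = regression_performance(t[va], forward(X[va], params))
        assert r2 >= 0.9

    def test_single_cell_search_returns_trained_model(self, rng):
        X = rng.uniform(0.1, 0.9, size=(40, 14))
        t = rng.uniform(0.4, 1.0, size=40)
        params, hist, val_rmse, h_sel = architecture_search(
            X[:30], t[:30], X[30:], t[30:], max_hidden=1, restarts=1,
            config=TrainingConfig(max_epochs=20), seed=0)
        assert h_sel == 1 and params.h == 1

    def test_deterministic_under_fixed_seed(self, rng):
        X = rng.uniform(0.1, 0.9, size=(40, 14))
        t = rng.uniform(0.4, 1.0, size=40)
        a = architecture_search(X[:30], t[:30], X[30:], t[30:], 2, 2,
                                TrainingConfig(max_epochs=15), seed=3)
        b = architecture_search(X[:30], t[:30], X[30:], t[30:], 2, 2,
                                TrainingConfig(max_epochs=15), seed=3)
        np.testing.assert_array_equal(a[0].to_vector(), b[0].to_vector())
        assert a[3] == b[3]
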