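"""Decoder: prediction algebra, NLMS behaviour, training-mode contracts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from myoreg.exceptions import ConfigurationError, InvalidInputError
from myoreg.features import FeatureVector
from myoreg.protocols import ProtocolSpec, enumerate_targets, protocol_sequence
from myoreg.regressor import (
    AdaptationConfig,
    CoefficientMatrix,
    load_coefficients,
    nlms_update,
    predict,
    save_coefficients,
    train_closed_loop,
    train_open_loop,
)
from myoreg.user import make_ideal_user


def _double_loop_predict(weights, x):
    """Independent brute-force oracle for y = B x."""
    out = []
    for i in range(weights.shape[0]):
        acc = 0.0
        for j in range(weights.shape[1]):
            acc += weights[i, j] * x[j]
        out.append(acc)
    return np.array(out)


def _linear_pairs(rng, n, noise=0.0):
    G = rng.normal(size=(3, 8))
    X = np.abs(rng.normal(0.5, 0.3, size=(n, 8)))  # positive, RMS-like
    D = X @ G.T + noise * rng.normal(size=(n, 3))
    return [(X[k], D[k]) for k in range(n)], G, X, D


class TestPredict:
    def test_zero_weights(self):
        B = CoefficientMatrix.zeros(8)
        assert np.array_equal(predict(B, np.ones(8)), np.zeros(3))

    def test_unit_selector(self):
        W = np.zeros((3, 8))
        W[0, 0] = 1.0
        x = np.zeros(8)
        x[0] = 1.0
        assert np.array_equal(predict(CoefficientMatrix(W), x), [1.0, 0.0, 0.0])

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(200):
            W = rng.uniform(-1, 1, size=(3, 8))
            x = rng.uniform(-1, 1, size=8)
            assert np.allclose(
                predict(CoefficientMatrix(W), x), _double_loop_predict(W, x), atol=1e-12
            )

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            predict(CoefficientMatrix.zeros(8), np.ones(5))

    @given(
        a=st.floats(-5, 5, allow_nan=False),
        b=st.floats(-5, 5, allow_nan=False),
    )
    def test_linearity(self, a, b):
        rng = np.random.default_rng(3)
        B = CoefficientMatrix(rng.normal(size=(3, 8)))
        x, z = rng.normal(size=8), rng.normal(size=8)
        lhs = predict(B, a * x + b * z)
        rhs = a * predict(B, x) + b * predict(B, z)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_accepts_feature_vector(self):
        B = CoefficientMatrix(np.eye(3, 8))
        fv = FeatureVector(np.arange(8.0))
        assert np.array_equal(predict(B, fv), [0.0, 1.0, 2.0])


class TestNlmsUpdate:
    def test_zero_error_is_fixed_point(self, rng):
        W = rng.normal(size=(3, 8))
        x = rng.uniform(0, 1, size=8)
        d = W @ x
        out = nlms_update(CoefficientMatrix(W), x, d)
        assert np.array_equal(out.weights, W)

    def test_single_step_hand_value(self):
        # mu=0.5, eps=0, x=e1, d=(1,0,0): only b_11 moves, to 0.5
        cfg = AdaptationConfig(learning_rate=0.5, regularizer=0.0)
        x = np.zeros(8)
        x[0] = 1.0
        out = nlms_update(CoefficientMatrix.zeros(8), x, np.array([1.0, 0, 0]), cfg)
        expected = np.zeros((3, 8))
        expected[0, 0] = 0.5
        assert np.array_equal(out.weights, expected)

    def test_per_dof_independence(self, rng):
        B = CoefficientMatrix(rng.normal(size=(3, 8)))
        x = rng.uniform(0, 1, size=8)
        d = predict(B, x)
        d2 = d.copy()
        d2[1] += 0.7  # error only in DoF 2
        out = nlms_update(B, x, d2)
        assert np.array_equal(out.weights[0], B.weights[0])
        assert np.array_equal(out.weights[2], B.weights[2])
        assert not np.array_equal(out.weights[1], B.weights[1])

    @given(mu=st.floats(0.01, 1.99))
    def test_repeated_sample_error_non_increasing(self, mu):
        cfg = AdaptationConfig(learning_rate=mu)
        rng = np.random.default_rng(5)
        B = CoefficientMatrix.zeros(8)
        x = rng.uniform(0.1, 1, size=8)
        d = np.array([1.0, -1.0, 0.5])
        prev = np.inf
        for _ in range(20):
            err = float(np.sum((d - predict(B, x)) ** 2))
            assert err <= prev + 1e-12
            prev = err
            B = nlms_update(B, x, d, cfg)

    def test_convergence_to_least_squares(self, rng):
        pairs, G, X, D = _linear_pairs(rng, 5000, noise=0.01)
        B = CoefficientMatrix.zeros(8)
        for x, d in pairs:
            B = nlms_update(B, x, d)
        ls, *_ = np.linalg.lstsq(X, D, rcond=None)
        rel = np.linalg.norm(B.weights - ls.T) / np.linalg.norm(ls.T)
        assert rel < 0.05

    def test_non_finite_input_skips_update(self, rng, caplog):
        B = CoefficientMatrix(rng.normal(size=(3, 8)))
        x = np.full(8, np.nan)
        out = nlms_update(B, x, np.ones(3))
        assert np.array_equal(out.weights, B.weights)
        assert "skipped" in caplog.text

    def test_invalid_learning_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            AdaptationConfig(learning_rate=2.0)


class TestTrainOpenLoop:
    def test_exact_recovery_on_noiseless_data(self, rng):
        pairs, G, X, D = _linear_pairs(rng, 600)
        B, trace = train_open_loop(pairs[:500], passes=3)
        held_x = X[500:]
        held_d = D[500:]
        mse = float(np.mean((held_x @ B.weights.T - held_d) ** 2))
        assert mse < 1e-4
        assert trace.shape == (1500,)
        assert trace[-1] < trace[0]

    def test_single_pair_geometric_contraction(self):
        x = np.zeros(8)
        x[0] = 2.0
        d = np.array([1.0, 0, 0])
        cfg = AdaptationConfig(learning_rate=1.0, regularizer=1e-12)
        B, trace = train_open_loop([(x, d)] * 30, cfg)
        # mu=1, eps->0: error annihilated after the first step
        assert trace[0] == pytest.approx(1.0)
        assert np.all(trace[1:] < 1e-12)

    def test_order_invariance_of_recovery(self, rng):
        pairs, G, X, D = _linear_pairs(rng, 600)
        shuffled = [pairs[k] for k in rng.permutation(600)]
        B1, _ = train_open_loop(pairs, passes=3)
        B2, _ = train_open_loop(shuffled, passes=3)
        for B in (B1, B2):
            mse = float(np.mean((X @ B.weights.T - D) ** 2))
            assert mse < 1e-4
        assert not np.array_equal(B1.weights, B2.weights)  # different trajectory

    def test_empty_pairs_rejected(self):
        with pytest.raises(InvalidInputError):
            train_open_loop([])


class TestTrainClosedLoop:
    def test_noiseless_protocol_ii_recovers_decoder(self):
        user = make_ideal_user(seed=1)
        prompts = protocol_sequence(ProtocolSpec("II", seed=3))
        B, log = train_closed_loop(prompts, user)
        probe = make_ideal_user(seed=1)
        for target in enumerate_targets(1):
            t = np.asarray(target, dtype=float)
            x = np.sqrt(np.mean(probe.emit_emg(t, 40) ** 2, axis=0))
            assert np.linalg.norm(predict(B, x) - t) < 0.05

    def test_zero_learning_rate_freezes_weights(self):
        user = make_ideal_user(seed=1)
        prompts = protocol_sequence(ProtocolSpec("II", seed=3))
        B, _ = train_closed_loop(prompts, user, AdaptationConfig(learning_rate=0.0))
        assert np.array_equal(B.weights, np.zeros((3, 8)))

    def test_seeded_sessions_are_bit_identical(self):
        prompts = protocol_sequence(ProtocolSpec("III", seed=9))
        runs = []
        for _ in range(2):
            from myoreg.user import make_virtual_user

            user = make_virtual_user(4, "medium")
            runs.append(train_closed_loop(prompts, user))
        (B1, log1), (B2, log2) = runs
        assert np.array_equal(B1.weights, B2.weights)
        assert np.array_equal(log1.features, log2.features)
        assert np.array_equal(log1.cursors, log2.cursors)

    def test_feedback_without_user_model_rejected(self):
        user = make_ideal_user(seed=1, feedback_gain=None)
        prompts = protocol_sequence(ProtocolSpec("III", seed=9))
        with pytest.raises(ConfigurationError, match="feedback"):
            train_closed_loop(prompts, user)


def test_coefficients_round_trip(tmp_path, rng):
    B = CoefficientMatrix(rng.normal(size=(3, 8)))
    path = tmp_path / "weights.csv"
    save_coefficients(path, B, {"protocol": "II"})
    back, meta = load_coefficients(path)
    assert np.array_equal(back.weights, B.weights)
    assert meta["protocol"] == "II"
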