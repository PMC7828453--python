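"""Forward pass, error, adaptive learning rate, momentum backpropagation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import locomode as lm
from locomode.ibpnn import (
    NetworkParams,
    TrainConfig,
    TrainState,
    backprop_step,
    error,
    forward,
    forward_batch,
    init_params,
    param_count,
    predict,
    predict_batch,
    sigmoid,
    train,
    update_alpha,
)


def numerical_gradient(p, x, y_hat, eps=1e-6):
    """Central-difference gradient of the half squared error w.r.t. every
    stored parameter — the independent oracle for backprop_step."""
    grads = {}
    for name in ("w_hidden", "theta_hidden", "w_out", "theta_out"):
        arr = getattr(p, name)
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = arr[i]
            arr[i] = orig + eps
            e_plus = error(forward(p, x)[1], y_hat)
            arr[i] = orig - eps
            e_minus = error(forward(p, x)[1], y_hat)
            arr[i] = orig
            g[i] = (e_plus - e_minus) / (2 * eps)
        grads[name] = g
    return grads


class TestSigmoidForward:
    def test_sigmoid_basic_values(self):
        assert sigmoid(0.0) == 0.5
        assert sigmoid(500.0) <= 1.0 and sigmoid(500.0) > 0.99
        assert sigmoid(-500.0) >= 0.0
        z = np.linspace(-5, 5, 11)
        np.testing.assert_allclose(sigmoid(z) + sigmoid(-z), 1.0)

    def test_zero_parameters_give_half_everywhere(self):
        p = NetworkParams(np.zeros((3, 4)), np.zeros(4), np.zeros((4, 2)), np.zeros(2))
        h, y = forward(p, np.array([0.3, -1.2, 9.0]))
        np.testing.assert_allclose(h, 0.5)
        np.testing.assert_allclose(y, 0.5)

    def test_scalar_network_hand_computed(self):
        # n=m=l=1, w=1, theta=0, x=0: h=f(0)=0.5, y=f(0.5)
        p = NetworkParams([[1.0]], [0.0], [[1.0]], [0.0])
        h, y = forward(p, np.array([0.0]))
        assert h[0] == pytest.approx(0.5)
        assert y[0] == pytest.approx(0.6224593312018546)

    def test_hidden_unit_permutation_symmetry(self):
        rng = np.random.default_rng(2)
        p = init_params(4, 5, 3, seed=2)
        x = rng.normal(size=4)
        perm = rng.permutation(5)
        q = NetworkParams(p.w_hidden[:, perm], p.theta_hidden[perm], p.w_out[perm, :], p.theta_out)
        np.testing.assert_allclose(forward(q, x)[1], forward(p, x)[1])

    def test_outputs_in_open_unit_interval(self):
        p = init_params(6, 8, 4, init_range=(-5, 5), seed=0)
        X = np.random.default_rng(1).normal(size=(20, 6))
        Y = forward_batch(p, X)
        assert np.all((Y > 0) & (Y < 1))

    def test_dimension_mismatch_rejected(self):
        p = init_params(3, 4, 2, seed=0)
        with pytest.raises(ValueError):
            forward(p, np.zeros(5))


class TestError:
    def test_zero_iff_equal(self):
        y = np.array([0.2, 0.8])
        assert error(y, y) == 0.0

    @pytest.mark.parametrize(
        "y,y_hat,expected",
        [((1, 0), (0, 1), 1.0), ((0.8, 0.2), (1, 0), 0.04)],
    )
    def test_hand_computed_values(self, y, y_hat, expected):
        assert error(np.array(y, float), np.array(y_hat, float)) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            error(np.zeros(2), np.zeros(3))


class TestAdaptiveAlpha:
    @pytest.mark.parametrize(
        "curr,prev,factor",
        [(2.0, 1.0, 0.99), (0.5, 1.0, 1.01), (1.02, 1.0, 1.0), (1.04, 1.0, 1.0), (1.0, 1.0, 1.0)],
    )
    def test_three_branches(self, curr, prev, factor):
        assert update_alpha(0.01, curr, prev) == pytest.approx(0.01 * factor)

    def test_alpha_stays_positive_and_bounded(self):
        rng = np.random.default_rng(0)
        alpha, alpha0, epochs = 0.05, 0.05, 200
        for _ in range(epochs):
            alpha = update_alpha(alpha, rng.uniform(0, 2), rng.uniform(0, 2))
            assert alpha > 0
        assert alpha0 * 0.99**epochs <= alpha <= alpha0 * 1.01**epochs


class TestBackpropStep:
    @pytest.mark.parametrize("arch", [(3, 4, 2), (5, 8, 3)])
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_numerical_gradient_without_momentum(self, arch, seed):
        """With beta = 0 every applied delta equals -alpha times the
        central-difference gradient of the half squared error."""
        rng = np.random.default_rng(seed)
        p = init_params(*arch, init_range=(-1, 1), seed=seed)
        x = rng.uniform(-1, 1, arch[0])
        y_hat = rng.uniform(0, 1, arch[2])
        oracle = numerical_gradient(p.copy(), x, y_hat)
        alpha = 0.1
        q = p.copy()
        state = TrainState.initial(q, alpha)
        backprop_step(q, x, y_hat, state, beta=0.0)
        for name in oracle:
            applied = getattr(q, name) - getattr(p, name)
            np.testing.assert_allclose(applied, -alpha * oracle[name], atol=1e-6)

    def test_zero_error_is_fixed_point(self):
        p = init_params(3, 4, 2, seed=1)
        x = np.array([0.1, 0.5, 0.9])
        _, y = forward(p, x)
        q = p.copy()
        state = TrainState.initial(q, 0.1)
        e = backprop_step(q, x, y.copy(), state, beta=0.0)
        assert e == 0.0
        np.testing.assert_array_equal(q.w_hidden, p.w_hidden)
        np.testing.assert_array_equal(q.w_out, p.w_out)

    def test_first_step_with_momentum_equals_no_momentum(self):
        # previous-step gradient slots start at zero, so beta is inert at t=0
        x = np.array([0.2, 0.7, 0.4])
        y_hat = np.array([1.0, 0.0])
        results = []
        for beta in (0.0, 0.9):
            p = init_params(3, 4, 2, seed=3)
            state = TrainState.initial(p, 0.1)
            backprop_step(p, x, y_hat, state, beta=beta)
            results.append(p.flatten())
        np.testing.assert_array_equal(results[0], results[1])

    def test_momentum_term_reuses_previous_step(self):
        # second step with beta > 0 must differ from beta = 0 by exactly
        # beta * alpha * (previous step's gradient terms)
        x1, x2 = np.array([0.2, 0.7, 0.4]), np.array([0.9, 0.1, 0.5])
        y_hat = np.array([1.0, 0.0])
        p_a = init_params(3, 4, 2, seed=3)
        st_a = TrainState.initial(p_a, 0.1)
        backprop_step(p_a, x1, y_hat, st_a, beta=0.0)
        prev = {k: getattr(st_a, k).copy() for k in ("g_w_out", "g_theta_out", "g_w_hidden", "g_theta_hidden")}
        p_b = p_a.copy()
        st_b = TrainState.initial(p_b, 0.1)
        st_b.__dict__.update({k: v.copy() for k, v in prev.items()})
        backprop_step(p_a, x2, y_hat, st_a, beta=0.0)
        backprop_step(p_b, x2, y_hat, st_b, beta=0.5)
        np.testing.assert_allclose(p_b.w_out - p_a.w_out, 0.5 * 0.1 * prev["g_w_out"], atol=1e-12)
        np.testing.assert_allclose(
            p_b.theta_hidden - p_a.theta_hidden, 0.5 * 0.1 * prev["g_theta_hidden"], atol=1e-12
        )

    def test_descent_on_repeated_pair(self):
        p = init_params(4, 6, 2, seed=5)
        x = np.random.default_rng(5).uniform(0, 1, 4)
        y_hat = np.array([0.0, 1.0])
        state = TrainState.initial(p, 0.05)
        errs = [backprop_step(p, x, y_hat, state, beta=0.0) for _ in range(50)]
        assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))


class TestTraining:
    def test_xor_learned_with_momentum_and_adaptive_rate(self, xor_dataset):
        cfg = TrainConfig(alpha0=0.5, beta=0.5, epochs=5000, seed=0)
        p0 = init_params(2, 4, 2, seed=0)
        p, hist = train(p0, xor_dataset, cfg)
        assert hist.epoch_error[-1] < 0.05
        np.testing.assert_array_equal(predict_batch(p, xor_dataset.X), xor_dataset.y)

    def test_history_length_and_determinism(self, xor_dataset):
        cfg = TrainConfig(alpha0=0.1, beta=0.5, epochs=1, seed=0)
        p0 = init_params(2, 3, 2, seed=0)
        _, h1 = train(p0, xor_dataset, cfg)
        assert len(h1) == 1
        cfg10 = TrainConfig(alpha0=0.1, beta=0.5, epochs=10, seed=4)
        _, ha = train(p0, xor_dataset, cfg10)
        _, hb = train(p0, xor_dataset, cfg10)
        assert ha.epoch_error == hb.epoch_error
        assert ha.alpha == hb.alpha

    def test_target_error_stops_early(self, xor_dataset):
        cfg = TrainConfig(alpha0=0.5, beta=0.5, epochs=5000, seed=0, target_error=0.05)
        p0 = init_params(2, 4, 2, seed=0)
        _, hist = train(p0, xor_dataset, cfg)
        assert len(hist) < 5000
        assert hist.epoch_error[-1] < 0.05

    def test_empty_dataset_rejected(self):
        ds = lm.Dataset(np.empty((0, 2)), np.empty(0, dtype=object), 200, y=np.empty(0, int), n_classes=2)
        with pytest.raises(ValueError):
            train(init_params(2, 3, 2, seed=0), ds, TrainConfig(epochs=1))

    def test_invalid_epoch_budget_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_alpha_positive_and_bounded_through_training(self, seed):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        ds = lm.Dataset(X, np.array(["Sit"] * 4, dtype=object), 200, y=np.array([0, 1, 1, 0]), n_classes=2)
        cfg = TrainConfig(alpha0=0.3, beta=0.2, epochs=15, seed=seed)
        _, hist = train(init_params(2, 3, 2, seed=seed), ds, cfg)
        alphas = np.array(hist.alpha)
        assert np.all(alphas > 0)
        assert np.all(alphas <= 0.3 * 1.01 ** np.arange(len(alphas)))
        assert np.all(alphas >= 0.3 * 0.99 ** np.arange(len(alphas)))


class TestPredictAndParams:
    def test_argmax_and_tie_rule(self):
        # network with zero weights and thresholds chosen to pin the outputs
        p = NetworkParams(np.zeros((2, 2)), np.zeros(2), np.zeros((2, 2)), np.array([0.0, 1.0]))
        # y = f(0.5*w - theta): y0 = f(0) = 0.5 > y1 = f(-1)... argmax 0
        assert predict(p, np.zeros(2)) == 0
        q = NetworkParams(np.zeros((2, 2)), np.zeros(2), np.zeros((2, 2)), np.zeros(2))
        assert predict(q, np.zeros(2)) == 0  # exact tie -> lowest index

    @pytest.mark.parametrize("arch,count", [((120, 10, 2), 1232), ((3, 4, 2), 26)])
    def test_parameter_count_enumeration(self, arch, count):
        assert param_count(*arch) == count
        p = init_params(*arch, seed=0)
        assert p.flatten().shape == (count,)

    def test_init_params_range_and_determinism(self):
        a = init_params(4, 5, 3, init_range=(-1, 1), seed=9)
        b = init_params(4, 5, 3, init_range=(-1, 1), seed=9)
        np.testing.assert_array_equal(a.flatten(), b.flatten())
        assert np.all(np.abs(a.flatten()) < 1)
        with pytest.raises(ValueError):
            init_params(2, 2, 2, init_range=(1, 1), seed=0)

    def test_flatten_unflatten_roundtrip(self):
        p = init_params(5, 7, 3, seed=11)
        q = NetworkParams.unflatten(p.flatten(), 5, 7, 3)
        np.testing.assert_array_equal(q.w_hidden, p.w_hidden)
        np.testing.assert_array_equal(q.theta_out, p.theta_out)

    def test_json_roundtrip(self, tmp_path):
        p = init_params(3, 4, 2, seed=1)
        path = tmp_path / "net.json"
        p.save(path, meta={"beta": 0.5})
        q = NetworkParams.load(path)
        np.testing.assert_array_equal(q.flatten(), p.flatten())
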