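import numpy as np
import pytest

from cxcompass import plasticity as plast
from cxcompass.network import build_layout
from cxcompass.readout import weight_correlation
from cxcompass._angles import wrap_rad


def _random_instance(rng, negative_W=True):
    W = -rng.random((18, 81)) * 1e-3 if negative_W else rng.normal(0, 1e-3, (18, 81))
    r = rng.random(81)
    c = rng.random(18) * 200.0
    return W, r, c


class TestInputCurrent:
    def test_zero_cases(self, rng):
        W, r, c = _random_instance(rng)
        assert np.allclose(plast.input_current(W, np.zeros(81)), 0.0)
        assert np.allclose(plast.input_current(np.zeros((18, 81)), r), 0.0)

    def test_single_term(self):
        W = np.zeros((18, 81))
        W[3, 10] = -0.5
        r = np.zeros(81)
        r[10] = 2.0
        I = plast.input_current(W, r)
        assert I[3] == pytest.approx(-1.0)
        assert np.all(I[np.arange(18) != 3] == 0.0)

    def test_nonpositive_for_nonneg_inputs(self, rng):
        W, r, c = _random_instance(rng)
        assert np.all(plast.input_current(W, r) <= 0.0)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            plast.input_current(np.zeros((18, 80)), np.zeros(81))


class TestHebbianRule:
    p = plast.HebbianParams()

    def test_presynaptic_gating(self, rng):
        W, r, c = _random_instance(rng)
        out = plast.hebbian_update(W, np.zeros(81), c, self.p)
        np.testing.assert_array_equal(out, W)

    def test_fixed_point(self):
        # w = a*c + b is stationary (before clipping)
        c = np.full(18, 50.0)
        W = np.full((18, 81), self.p.a * 50.0 + self.p.b)
        out = plast.hebbian_update(W, np.ones(81), c, self.p, clip=False)
        np.testing.assert_allclose(out, W)

    def test_hand_computed_update(self):
        # eta=0.29, a=1.7e-6, b=1.7e-4, r=1, c=50, w=0:
        # dw = 0.29 * (1.7e-6*50 + 1.7e-4 - 0) = 0.29 * 2.55e-4 = 7.395e-5
        W = np.zeros((18, 81))
        r = np.zeros(81); r[0] = 1.0
        c = np.zeros(18); c[0] = 50.0
        out = plast.hebbian_update(W, r, c, self.p, clip=False)
        assert out[0, 0] == pytest.approx(0.29 * (8.5e-5 + 1.7e-4), rel=1e-12)
        assert out[0, 0] == pytest.approx(7.395e-5, rel=1e-10)

    def test_clip_keeps_nonpositive(self, rng):
        W, r, c = _random_instance(rng)
        out = plast.hebbian_update(W, r, c, self.p, dt=100.0)
        assert np.all(out <= 0.0)

    def test_convergence_to_clipped_fixed_point(self):
        # with stationary r, c the weights approach clip(a*c + b) = 0 at
        # geometric rate eta*r per unit time
        rng = np.random.default_rng(1)
        W = plast.random_init_weights(rng)
        r = np.full(81, 0.5)
        c = np.full(18, 100.0)
        target = self.p.a * 100.0 + self.p.b
        dists = []
        for _ in range(200):
            W = plast.hebbian_update(W, r, c, self.p, dt=0.05, clip=False)
            dists.append(np.abs(W - target).max())
        W = plast.clip_nonpositive(W)
        ratio = dists[100] / dists[99]
        assert ratio == pytest.approx(1.0 - self.p.eta * 0.5 * 0.05, rel=1e-6)
        assert np.all(W == 0.0)  # positive pre-clip target clips to zero


class TestGradientEquivalence:
    """The rules are gradient descent on their objectives (central
    finite-difference oracle, holding the postsynaptic trace fixed)."""

    def _numeric_grad(self, f, W, eps=1e-5):
        # central differences are exact for these quadratic objectives up
        # to roundoff; a larger eps keeps the roundoff term small
        G = np.zeros_like(W)
        it = np.nditer(W, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            Wp, Wm = W.copy(), W.copy()
            Wp[idx] += eps
            Wm[idx] -= eps
            G[idx] = (f(Wp) - f(Wm)) / (2 * eps)
        return G

    def test_hebbian_descends_its_objective(self, rng):
        p = plast.HebbianParams()
        W = -rng.random((3, 5))  # small instance for the O(nm) oracle
        r = rng.random(5)
        c = rng.random(3) * 100.0

        def phi(Wx):
            I = np.einsum("m,nm->n", r, Wx)
            return -p.a * np.sum(c * I) + 0.5 * np.sum(r * (p.b - Wx) ** 2)

        G = self._numeric_grad(phi, W)
        dW = p.eta * r[None, :] * (p.a * c[:, None] + p.b - W)
        np.testing.assert_allclose(dW / p.eta, -G, rtol=1e-6, atol=1e-12)

    def test_errmin_descends_its_objective(self, rng):
        p = plast.ErrorMinParams()
        W = -rng.random((3, 5))
        r = rng.random(5)
        c = rng.random(3) * 100.0

        def phi(Wx):
            I = np.einsum("m,nm->n", r, Wx)
            return np.sum((c - p.beta * I) ** 2)

        G = self._numeric_grad(phi, W)
        I = np.einsum("m,nm->n", r, W)
        dW = p.eta * r[None, :] * (c - p.beta * I)[:, None]
        # dW = -(eta / 2 beta) * grad
        np.testing.assert_allclose(dW, -(p.eta / (2 * p.beta)) * G, rtol=1e-6)

    def test_objective_values_on_full_shapes(self, rng):
        W, r, c = _random_instance(rng)
        p = plast.HebbianParams()
        assert plast.hebbian_objective(np.zeros((18, 81)), np.zeros(81), c, p.a, p.b) == 0.0
        assert plast.hebbian_objective(np.full((18, 81), p.b), r, c, 0.0, p.b) == pytest.approx(0.0)
        assert plast.errmin_objective(W, r, c, 0.0) == pytest.approx(np.sum(c**2))
        assert plast.errmin_objective(W, r, c, 0.0025) >= 0.0

    def test_errmin_fixed_point(self, rng):
        # c = beta * I gives zero update
        p = plast.ErrorMinParams()
        W, r, _ = _random_instance(rng)
        c = p.beta * plast.input_current(W, r)
        out = plast.errmin_update(W, r, c, p, clip=False)
        np.testing.assert_allclose(out, W)


class TestClip:
    def test_examples(self):
        W = np.array([[-0.2, 0.1], [0.0, -0.0]])
        out = plast.clip_nonpositive(W)
        np.testing.assert_array_equal(out, [[-0.2, 0.0], [0.0, 0.0]])
        np.testing.assert_array_equal(plast.clip_nonpositive(out), out)  # idempotent


class TestTargetActivity:
    layout = build_layout()

    def test_peak_at_preferred_angle(self):
        th = self.layout.preferred_angles
        c = plast.target_compass_activity(np.array([th[2]]), th)
        assert np.argmax(c[0][:8]) == 2

    def test_hemispheres_share_targets(self):
        th = self.layout.preferred_angles
        c = plast.target_compass_activity(np.array([0.7, -1.1]), th)
        np.testing.assert_allclose(c[:, :9], c[:, 9:])

    def test_shift_equivariance(self):
        # shifting all headings by one ring position permutes the targets
        # between neurons whose preferred angles map onto each other
        th = self.layout.preferred_angles
        h = np.linspace(-np.pi, np.pi, 50)
        delta = 2 * np.pi / 8
        c0 = plast.target_compass_activity(h, th)
        c1 = plast.target_compass_activity(h + delta, th)
        for n in range(18):
            partners = np.flatnonzero(
                np.abs(wrap_rad(th - (th[n] + delta))) < 1e-9
            )
            np.testing.assert_allclose(c1[:, partners[0]], c0[:, n], atol=1e-12)


class TestOfflineSolver:
    def test_parameter_recovery_at_zero_penalty(self):
        # data generated exactly by the model is recovered by the fit
        rng = np.random.default_rng(3)
        T = 500
        X = rng.random((T, 81)) * 100.0
        W_true = np.zeros((18, 81))
        W_true[:, rng.choice(81, 10, replace=False)] = rng.random((18, 10)) * 2.0
        drive = X @ W_true.T
        alpha_true = -(drive.max(axis=0) + rng.random(18) * 100.0)
        C = -drive - alpha_true  # c = -alpha - r . w~, all >= 0
        assert np.all(C >= 0)
        spec = plast.OfflineFitSpec(lambda_=0.0, beta_scale=0.0025)
        W, info = plast.optimize_weights_offline(X, C, spec)
        np.testing.assert_allclose(-W / 0.0025, W_true, atol=2e-3 * W_true.max())
        np.testing.assert_allclose(info["intercepts"], alpha_true, rtol=1e-3)

    def test_huge_penalty_gives_zero_weights(self, rng):
        X = rng.random((200, 81))
        C = rng.random((200, 18)) * 100.0
        W, _ = plast.optimize_weights_offline(
            X, C, plast.OfflineFitSpec(lambda_=1e12)
        )
        np.testing.assert_array_equal(W, 0.0)

    def test_sign_convention(self, rng):
        X = rng.random((200, 81)) * 100.0
        C = rng.random((200, 18)) * 100.0
        W, _ = plast.optimize_weights_offline(X, C, plast.OfflineFitSpec(lambda_=10.0))
        assert np.all(W <= 0.0)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            plast.optimize_weights_offline(
                np.zeros((200, 81)), np.ones((200, 18)), plast.OfflineFitSpec(lambda_=1.0)
            )
        with pytest.raises(ValueError):
            plast.optimize_weights_offline(
                np.ones((50, 81)), np.ones((50, 18)), plast.OfflineFitSpec(lambda_=1.0)
            )  # too few samples

    def test_residual_nonincreasing_in_nested_data(self, rng):
        # adding samples cannot reduce the total residual of the smaller fit
        X = rng.random((400, 81)) * 10.0
        C = rng.random((400, 18)) * 50.0
        spec = plast.OfflineFitSpec(lambda_=1.0)
        _, info_small = plast.optimize_weights_offline(X[:200], C[:200], spec)
        _, info_big = plast.optimize_weights_offline(X, C, spec)
        assert info_big["residuals"].sum() >= info_small["residuals"].sum() - 1e-6

    def test_lambda_cv_returns_candidate(self, rng):
        X = rng.random((300, 81)) * 50.0
        C = rng.random((300, 18)) * 50.0
        lam = plast.choose_lambda_cv(X, C, candidates=np.array([1.0, 1e6]))
        assert lam in (1.0, 1e6)


def test_random_init_range():
    rng = np.random.default_rng(0)
    W = plast.random_init_weights(rng)
    assert W.shape == (18, 81)
    assert np.all(W <= 0.0) and np.all(W >= -1.7e-4)


def test_weight_correlation_of_learned_vs_optimal_is_defined(rng):
    # smoke: flattened product-moment correlation over full-size matrices
    A = -rng.random((18, 81))
    B = -rng.random((18, 81))
    assert -1.0 <= weight_correlation(A, B) <= 1.0
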