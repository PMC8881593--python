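"""Plastic ring -> E-PG weights: online learning rules, their objective
functions, and the offline optimal-weight solver.

The 18 x 81 weight matrix W (element ``w[n, m]`` from ring neuron m to
E-PG neuron n) is the only plastic structure in the circuit.  Ring neurons
are inhibitory, so every weight is clipped non-positive; visual input acts
on the compass by *disinhibition* -- the least-inhibited E-PG neurons win.

Two online rules are provided, both presynaptically gated:

- the Hebbian rule  ``dw = eta * r * (a*c + b - w)``, which performs
  gradient descent on an overlap-plus-regularizer objective;
- the error-minimizing rule  ``dw = eta * r * (c - beta * I)`` with
  ``I_n = sum_m r_m w_nm``, which performs gradient descent on the squared
  mismatch between compass activity and scaled ring input current.

The offline solver fits non-negative weights by lasso-regularized
regression of target compass activity on ring activity, then returns the
sign-flipped, ``beta_scale``-scaled matrix used in simulation.

All operations broadcast over leading batch axes (r ``(..., 81)``,
c ``(..., 18)``, W ``(..., 18, 81)``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear

from ._angles import wrap_rad

__all__ = [
    "HebbianParams",
    "ErrorMinParams",
    "OfflineFitSpec",
    "input_current",
    "hebbian_update",
    "hebbian_objective",
    "errmin_update",
    "errmin_objective",
    "target_compass_activity",
    "optimize_weights_offline",
    "choose_lambda_cv",
    "clip_nonpositive",
    "random_init_weights",
]

N_EPG, N_RING = 18, 81


@dataclass(frozen=True)
class HebbianParams:
    """Presynaptically-gated Hebbian rule constants.

    ``eta`` is a per-second learning rate at unit presynaptic activation
    (scaled by the step size through the ``dt`` argument of
    :func:`hebbian_update`); ``a`` converts postsynaptic trace (Hz) to the
    weight scale; ``b`` is the activity-independent weight attractor.
    """

    eta: float = 0.29
    a: float = 1.7e-6
    b: float = 1.7e-4

    def __post_init__(self):
        if self.eta <= 0:
            raise ValueError("eta must be positive")


@dataclass(frozen=True)
class ErrorMinParams:
    """Error-minimizing rule constants: learning rate ``eta`` (per second
    at unit presynaptic activation) and current-to-activity scaling
    ``beta`` (shared by default with the offline solver's 0.0025)."""

    eta: float = 0.29
    beta: float = 0.0025

    def __post_init__(self):
        if self.eta <= 0 or self.beta <= 0:
            raise ValueError("eta and beta must be positive")


def input_current(W: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Total ring input current per E-PG neuron: I_n = sum_m r_m w_nm."""
    W = np.asarray(W, dtype=float)
    r = np.asarray(r, dtype=float)
    if W.shape[-2:] != (N_EPG, N_RING) or r.shape[-1] != N_RING:
        raise ValueError(f"shape mismatch: W {W.shape}, r {r.shape}")
    return np.einsum("...m,...nm->...n", r, W)


def hebbian_update(
    W: np.ndarray, r: np.ndarray, c: np.ndarray, p: HebbianParams,
    dt: float = 1.0, clip: bool = True,
) -> np.ndarray:
    """One step of the presynaptically-gated Hebbian rule.

    dw[n, m] = eta * dt * r[m] * (a * c[n] + b - w[n, m]), then clipped
    non-positive.  With ``dt=1`` this is the literal discrete rule.
    """
    W = np.asarray(W, dtype=float)
    target = p.a * np.asarray(c, dtype=float)[..., :, None] + p.b
    dW = p.eta * dt * np.asarray(r, dtype=float)[..., None, :] * (target - W)
    out = W + dW
    return np.minimum(out, 0.0) if clip else out


def hebbian_objective(
    W: np.ndarray, r: np.ndarray, c: np.ndarray, a: float, b: float
) -> float | np.ndarray:
    """Objective the Hebbian rule descends (holding c fixed):

    phi = -a * sum_n c_n I_n + 1/2 * sum_nm r_m (b - w_nm)^2
    """
    I = input_current(W, r)
    overlap = -a * np.sum(np.asarray(c, dtype=float) * I, axis=-1)
    reg = 0.5 * np.sum(
        np.asarray(r, dtype=float)[..., None, :]
        * (b - np.asarray(W, dtype=float)) ** 2,
        axis=(-2, -1),
    )
    out = overlap + reg
    return out if np.ndim(out) else float(out)


def errmin_update(
    W: np.ndarray, r: np.ndarray, c: np.ndarray, p: ErrorMinParams,
    dt: float = 1.0, clip: bool = True,
) -> np.ndarray:
    """One step of the error-minimizing rule.

    dw[n, m] = eta * dt * r[m] * (c[n] - beta * I_n), then clipped
    non-positive; I_n is the ring input current.
    """
    W = np.asarray(W, dtype=float)
    err = np.asarray(c, dtype=float) - p.beta * input_current(W, r)
    dW = p.eta * dt * np.asarray(r, dtype=float)[..., None, :] * err[..., :, None]
    out = W + dW
    return np.minimum(out, 0.0) if clip else out


def errmin_objective(
    W: np.ndarray, r: np.ndarray, c: np.ndarray, beta: float
) -> float | np.ndarray:
    """Squared-mismatch objective: phi' = sum_n (c_n - beta * I_n)^2."""
    I = input_current(W, r)
    out = np.sum((np.asarray(c, dtype=float) - beta * I) ** 2, axis=-1)
    return out if np.ndim(out) else float(out)


def clip_nonpositive(W: np.ndarray) -> np.ndarray:
    """Enforce the inhibitory sign convention: elementwise min(w, 0)."""
    return np.minimum(np.asarray(W, dtype=float), 0.0)


def random_init_weights(
    rng: np.random.Generator, scale: float = 1.7e-4, shape=(N_EPG, N_RING)
) -> np.ndarray:
    """Random initial weights for online learning: i.i.d. uniform on
    [-scale, 0], with scale anchored to the Hebbian offset ``b``."""
    return -rng.random(shape) * scale


def target_compass_activity(
    headings: np.ndarray,
    preferred_angles: np.ndarray,
    amplitude: float = 10000.0,
    sigma: float = np.deg2rad(40.0),
) -> np.ndarray:
    """Supervised target for the offline fit: (T, 18) activations where
    neuron n follows a circular Gaussian profile of width ``sigma`` (one
    glomerulus by default) around its preferred angle, peak ``amplitude``
    (Hz, matched to the E-PG trace scale)."""
    h = np.asarray(headings, dtype=float)[:, None]
    dev = wrap_rad(h - np.asarray(preferred_angles, dtype=float)[None, :])
    return amplitude * np.exp(-0.5 * (dev / sigma) ** 2)


@dataclass(frozen=True)
class OfflineFitSpec:
    """Offline solver configuration.

    ``lambda_``: lasso penalty on the non-negative pre-sign-flip weights
    (None = choose by blocked cross-validation); ``beta_scale``: the
    final scaling of the sign-flipped weights (0.0025); target profile
    amplitude (Hz) and width (radians).
    """

    lambda_: float | None = None
    beta_scale: float = 0.0025
    target_amplitude: float = 10000.0
    target_sigma: float = np.deg2rad(40.0)

    def __post_init__(self):
        if self.lambda_ is not None and self.lambda_ < 0:
            raise ValueError("lambda must be non-negative")


def _fit_positive_lasso(
    X: np.ndarray, y: np.ndarray, lambda_: float
) -> tuple[np.ndarray, float]:
    """min over w >= 0, alpha of  sum_t (y_t - X_t w - alpha)^2 + lambda * sum w."""
    T = len(y)
    if lambda_ == 0.0:
        # Exact bounded least squares: weights >= 0, free intercept.
        A = np.column_stack([X, np.ones(T)])
        lb = np.concatenate([np.zeros(X.shape[1]), [-np.inf]])
        res = lsq_linear(A, y, bounds=(lb, np.inf), method="bvls", tol=1e-12)
        return res.x[:-1], float(res.x[-1])
    import warnings

    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import Lasso

    # sklearn objective: (1/2T)||y - Xw - a||^2 + alpha * ||w||_1
    model = Lasso(
        alpha=lambda_ / (2.0 * T), positive=True, fit_intercept=True,
        max_iter=3000, tol=1e-5,
    )
    with warnings.catch_warnings():
        # approximate coordinate-descent solutions are acceptable here
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model.coef_, float(model.intercept_)


def optimize_weights_offline(
    r_timeseries: np.ndarray,
    c_target: np.ndarray,
    spec: OfflineFitSpec = OfflineFitSpec(),
) -> tuple[np.ndarray, dict]:
    """Fit the optimal non-positive ring -> E-PG weights.

    Per E-PG neuron n, solves the positive-lasso problem

        min_{w~ >= 0, alpha_n}  sum_t (c~_n(t) - sum_m (-r_m(t) w~_nm)
                                + alpha_n)^2 + lambda * sum_m w~_nm

    i.e. compass activity is modelled as a baseline minus ring-driven
    inhibition.  The simulation-ready matrix is the sign-flipped, scaled
    ``W = -beta_scale * w~``.

    Returns ``(W, info)`` where info carries intercepts, the lambda used,
    and per-neuron residuals.
    """
    X = np.asarray(r_timeseries, dtype=float)
    C = np.asarray(c_target, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_RING:
        raise ValueError(f"r_timeseries must be (T, {N_RING})")
    if C.shape != (X.shape[0], N_EPG):
        raise ValueError("c_target must be (T, 18) aligned with r_timeseries")
    if X.shape[0] < N_RING:
        raise ValueError("need at least 81 time samples to fit 81 weights")
    if not np.any(X > 0):
        raise ValueError("degenerate design: ring activity is identically zero")

    lambda_ = spec.lambda_
    if lambda_ is None:
        # cross-validate on a thinned slice, then rescale the per-sample
        # penalty to the full sample count
        thin = max(1, X.shape[0] // 2000)
        lam_thin = choose_lambda_cv(X[::thin], C[::thin])
        lambda_ = lam_thin * (X.shape[0] / len(X[::thin]))

    W_tilde = np.zeros((N_EPG, N_RING))
    intercepts = np.zeros(N_EPG)
    residuals = np.zeros(N_EPG)
    for n in range(N_EPG):
        y = -C[:, n]
        w, a = _fit_positive_lasso(X, y, lambda_)
        W_tilde[n] = w
        intercepts[n] = a  # alpha_n: c~ = -(r . w~) - alpha at zero residual
        residuals[n] = float(np.sum((y - X @ w - a) ** 2))
    W = clip_nonpositive(-spec.beta_scale * W_tilde)
    info = {
        "lambda": float(lambda_),
        "intercepts": intercepts,
        "residuals": residuals,
        "w_tilde": W_tilde,
    }
    return W, info


def choose_lambda_cv(
    X: np.ndarray,
    C: np.ndarray,
    candidates: np.ndarray | None = None,
    n_folds: int = 5,
) -> float:
    """Pick the lasso penalty by blocked (contiguous-fold) cross-validation,
    scoring mean squared prediction error across all E-PG targets."""
    T = X.shape[0]
    if candidates is None:
        # per-sample penalties (sklearn-alpha equivalents 10, 100, 1000)
        candidates = 2.0 * T * np.array([10.0, 100.0, 1000.0])
    bounds = np.linspace(0, T, n_folds + 1, dtype=int)
    best_lam, best_err = float(candidates[0]), np.inf
    for lam in candidates:
        err = 0.0
        for f in range(n_folds):
            lo, hi = bounds[f], bounds[f + 1]
            test = np.zeros(T, dtype=bool)
            test[lo:hi] = True
            Xtr, Xte = X[~test], X[test]
            for n in range(C.shape[1]):
                w, a = _fit_positive_lasso(Xtr, -C[~test, n], float(lam))
                err += float(np.mean((-C[test, n] - Xte @ w - a) ** 2))
        if err < best_err:
            best_err, best_lam = err, float(lam)
    return best_lam
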