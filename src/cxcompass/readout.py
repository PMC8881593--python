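"""Heading decoding, path integration, and trial metrics.

The heading estimate is the population vector of the E-PG activity bump:
each neuron contributes a unit vector at its preferred angle weighted by
its low-pass-filtered spike trace; the estimate is the angle of the sum
and the confidence its resultant length.  Position is dead-reckoned from
decoded heading and (known) linear speed.
"""

from __future__ import annotations

import numpy as np

from ._angles import wrap_rad

__all__ = [
    "decode_heading",
    "path_integrate",
    "circular_rmse",
    "unwrapped_rmse",
    "position_error_pct",
    "weight_correlation",
    "bootstrap_ci",
]


def decode_heading(
    epg_traces: np.ndarray,
    preferred_angles: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Population-vector decode of E-PG activity.

    ``epg_traces``: (..., 18) non-negative activation traces (the two
    hemispheres share preferred angles and are effectively summed by the
    vector sum).  ``weights`` optionally down-weights neurons whose
    preferred angle is represented more than once (the duplicated
    endpoint glomerulus).  Returns ``(heading, confidence)`` where
    heading is in radians wrapped to (-pi, pi] and confidence is the
    resultant length normalized to [0, 1].  An all-zero trace vector
    yields NaN heading and zero confidence (undecodable, flagged not
    silent).
    """
    tr = np.asarray(epg_traces, dtype=float)
    th = np.asarray(preferred_angles, dtype=float)
    if tr.shape[-1] != th.shape[-1]:
        raise ValueError("trace / preferred-angle length mismatch")
    if weights is not None:
        tr = tr * np.asarray(weights, dtype=float)
    x = np.sum(tr * np.cos(th), axis=-1)
    y = np.sum(tr * np.sin(th), axis=-1)
    total = np.sum(tr, axis=-1)
    heading = np.where(total > 0, np.arctan2(y, x), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        confidence = np.where(total > 0, np.hypot(x, y) / np.where(total > 0, total, 1.0), 0.0)
    return wrap_rad(heading) if heading.ndim else float(wrap_rad(heading)), confidence


def path_integrate(
    headings: np.ndarray, linear_speed: np.ndarray, dt: float,
    origin=(0.0, 0.0),
) -> np.ndarray:
    """Dead-reckon position from heading and speed:

    position[t+1] = position[t] + dt * speed[t] * (cos h[t], sin h[t]).

    ``headings`` may carry leading batch axes (..., T); returns (..., T, 2)
    with position[..., 0, :] = origin.
    """
    h = np.asarray(headings, dtype=float)
    v = np.asarray(linear_speed, dtype=float)
    v = np.broadcast_to(v, h.shape)
    if h.shape != v.shape:
        raise ValueError("heading / speed length mismatch")
    steps = dt * v[..., :-1, None] * np.stack(
        [np.cos(h[..., :-1]), np.sin(h[..., :-1])], axis=-1
    )
    pos = np.concatenate(
        [np.zeros(h.shape[:-1] + (1, 2)), np.cumsum(steps, axis=-2)], axis=-2
    )
    return pos + np.asarray(origin, dtype=float)


def circular_rmse(est: np.ndarray, truth: np.ndarray) -> float | np.ndarray:
    """RMSE of the wrapped angular error, radians.  NaN estimates (e.g.
    undecodable instants) are excluded."""
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.shape != np.broadcast_shapes(est.shape, truth.shape):
        truth = np.broadcast_to(truth, est.shape)
    if est.shape[-1] == 0:
        raise ValueError("empty heading series")
    err = wrap_rad(est - truth)
    out = np.sqrt(np.nanmean(err**2, axis=-1))
    return out if np.ndim(out) else float(out)


def unwrapped_rmse(est: np.ndarray, truth: np.ndarray) -> float | np.ndarray:
    """RMSE of the cumulative (unwrapped) angular error: the wrapped
    per-step error increments are re-integrated so that full-turn slips
    accumulate instead of aliasing."""
    est = np.asarray(est, dtype=float)
    truth = np.broadcast_to(np.asarray(truth, dtype=float), est.shape)
    err = wrap_rad(est - truth)
    err = np.where(np.isnan(err), 0.0, err)
    steps = wrap_rad(np.diff(err, axis=-1))
    cum = np.concatenate([err[..., :1], err[..., :1] + np.cumsum(steps, axis=-1)], axis=-1)
    out = np.sqrt(np.mean(cum**2, axis=-1))
    return out if np.ndim(out) else float(out)


def position_error_pct(
    est_positions: np.ndarray, truth_positions: np.ndarray
) -> float | np.ndarray:
    """Mean instantaneous position error as a percentage of the total
    ground-truth path length."""
    est = np.asarray(est_positions, dtype=float)
    truth = np.asarray(truth_positions, dtype=float)
    truth = np.broadcast_to(truth, est.shape)
    path_len = np.sum(
        np.linalg.norm(np.diff(truth, axis=-2), axis=-1), axis=-1
    )
    if np.any(path_len <= 0):
        raise ValueError("ground-truth path length must be positive")
    err = np.mean(np.linalg.norm(est - truth, axis=-1), axis=-1)
    out = 100.0 * err / path_len
    return out if np.ndim(out) else float(out)


def weight_correlation(W_learned: np.ndarray, W_optimal: np.ndarray) -> float | np.ndarray:
    """Product-moment correlation between two weight matrices over their
    flattened elements; broadcasts over leading batch axes of W_learned."""
    A = np.asarray(W_learned, dtype=float)
    B = np.asarray(W_optimal, dtype=float)
    if A.shape[-2:] != B.shape[-2:]:
        raise ValueError("weight matrices must share their trailing shape")
    a = A.reshape(*A.shape[:-2], -1)
    b = B.reshape(*B.shape[:-2], -1)
    a = a - a.mean(axis=-1, keepdims=True)
    b = b - b.mean(axis=-1, keepdims=True)
    sa = np.sqrt(np.sum(a**2, axis=-1))
    sb = np.sqrt(np.sum(b**2, axis=-1))
    if np.any(sa == 0) or np.any(sb == 0):
        raise ValueError("correlation undefined for a constant weight matrix")
    out = np.sum(a * np.broadcast_to(b, a.shape), axis=-1) / (sa * sb)
    return out if np.ndim(out) else float(out)


def bootstrap_ci(
    values: np.ndarray,
    rng: np.random.Generator,
    n_resamples: int = 1000,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the mean."""
    v = np.asarray(values, dtype=float)
    idx = rng.integers(0, len(v), size=(n_resamples, len(v)))
    means = v[idx].mean(axis=1)
    lo = float(np.quantile(means, (1 - level) / 2))
    hi = float(np.quantile(means, 1 - (1 - level) / 2))
    return lo, hi
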