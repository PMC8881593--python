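"""Figure helpers: activity rasters, decoded-versus-truth heading, and
error-over-time bands."""

from __future__ import annotations

import numpy as np

from ._angles import wrap_rad

__all__ = ["plot_bump_raster", "plot_heading_comparison", "plot_error_bands", "plot_weight_matrix"]


def plot_bump_raster(results, seed_index: int = 0, ax=None):
    """E-PG activation-trace raster over time for one seed (requires a fit
    with ``record_traces=True``)."""
    import matplotlib.pyplot as plt

    run = results.run
    if run.epg_trace is None:
        raise ValueError("fit was run without record_traces=True")
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    img = run.epg_trace[seed_index].T  # (18, T)
    ax.imshow(
        img, aspect="auto", origin="lower", interpolation="none",
        extent=[run.t[0], run.t[-1], -0.5, 17.5], cmap="viridis",
    )
    ax.set(xlabel="time (s)", ylabel="E-PG neuron", title="activity bump")
    return ax


def plot_heading_comparison(results_by_config: dict, trajectory, ax=None, seed_index: int = 0):
    """Decoded heading of each configuration against ground truth."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.plot(trajectory.t, trajectory.heading, "k-", lw=1.2, label="ground truth")
    for name, res in results_by_config.items():
        ax.plot(res.run.t, res.run.est_heading[seed_index], ".", ms=0.8, label=name)
    ax.set(xlabel="time (s)", ylabel="heading (rad)")
    ax.legend(loc="upper right", fontsize=8, markerscale=8)
    return ax


def plot_error_bands(results_by_config: dict, trajectory, ax=None, window: float = 1.0):
    """Mean +- s.d. of the absolute wrapped orientation error over time,
    per configuration, smoothed over ``window`` seconds."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    dt = trajectory.dt
    k = max(1, int(round(window / dt)))
    kernel = np.ones(k) / k
    for name, res in results_by_config.items():
        err = np.abs(wrap_rad(res.run.est_heading - trajectory.heading))
        sm = np.apply_along_axis(lambda x: np.convolve(x, kernel, mode="same"), 1, err)
        mean, sd = sm.mean(axis=0), sm.std(axis=0)
        ax.plot(trajectory.t, mean, label=name)
        ax.fill_between(trajectory.t, mean - sd, mean + sd, alpha=0.25)
    ax.set(xlabel="time (s)", ylabel="|orientation error| (rad)")
    ax.legend(loc="upper left", fontsize=8)
    return ax


def plot_weight_matrix(W, ax=None, title: str = "ring -> E-PG weights"):
    """Heatmap of an 18 x 81 weight matrix, landmark sub-populations marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    im = ax.imshow(W, aspect="auto", interpolation="none", cmap="magma_r")
    for edge in (26.5, 53.5):
        ax.axvline(edge, color="w", lw=0.8)
    ax.set(xlabel="ring neuron", ylabel="E-PG neuron", title=title)
    plt.colorbar(im, ax=ax, shrink=0.8)
    return ax
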