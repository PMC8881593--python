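"""Model / Results interface tying the circuit together.

:class:`HeadingModel` is built from data (a :class:`~cxcompass.environment.World`
and a :class:`~cxcompass.environment.Trajectory`, or a recorded sensor
table); ``fit()`` runs the spiking simulation under one of the three
weight configurations and returns a :class:`HeadingResults` carrying the
decoded heading, per-seed error metrics, learned weights and diagnostics,
with a ``summary()`` table.  ``run_experiment`` evaluates all three
configurations across seeds with bootstrap intervals and rank-sum tests.

Simulations are batched across seeds: one vectorized pass integrates all
seeds' networks simultaneously, with every source of randomness drawn
from per-seed child generators of a single top-level seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import network as net
from . import plasticity as plast
from . import readout
from ._angles import wrap_rad
from .encoding import (
    AngularVelocityEncoder,
    NoiseModel,
    RingTuningBank,
    pen_drive,
    ring_drive,
)
from .environment import Trajectory, World, trajectory_bearings
from .network import LIFParams

__all__ = [
    "ModelConfig",
    "HeadingModel",
    "HeadingResults",
    "ExperimentConfig",
    "RunMetrics",
    "run_experiment",
]

CONFIGURATIONS = ("optimal", "online", "av_only")


@dataclass(frozen=True)
class ModelConfig:
    """All tunable circuit parameters in one place.

    ``ring_rate_max`` (Hz) sets the activation scale of ring neurons: the
    synaptic current into E-PG is (ring rate in Hz) x W, while the
    learning rules gate on the normalized activation (rate / ring_rate_max)
    with per-second learning rates.  ``epg_bias`` is the constant
    excitatory current to E-PG against which non-positive ring weights act
    by disinhibition.
    """

    lif: LIFParams = field(default_factory=LIFParams)
    bank: RingTuningBank = field(default_factory=RingTuningBank)
    av_enc: AngularVelocityEncoder = field(default_factory=AngularVelocityEncoder)
    noise: NoiseModel = field(default_factory=NoiseModel)
    hebbian: plast.HebbianParams = field(default_factory=plast.HebbianParams)
    errmin: plast.ErrorMinParams = field(default_factory=plast.ErrorMinParams)
    offline: plast.OfflineFitSpec = field(default_factory=plast.OfflineFitSpec)
    ring_mode: str = "rate"           # 'rate' or 'spiking'
    ring_rate_max: float = 250.0      # Hz at a receptive-field centre
    vis_gain: float = 1.0             # ring -> E-PG current per (Hz x weight)
    epg_bias: float = 0.3             # constant E-PG excitation (current units)
    learn_every: int = 1              # steps between weight updates
    learn_gain: float = 0.5           # activity-unit conversion for the
                                      # learning gate (calibrated so a trial
                                      # ends mid-transient, not clipped out)
    corr_sample_dt: float = 1.0       # s between weight-correlation samples

    def __post_init__(self):
        if self.ring_mode not in ("rate", "spiking"):
            raise ValueError("ring_mode must be 'rate' or 'spiking'")


@dataclass
class SimulationRun:
    """Raw batched simulation record for one configuration."""

    configuration: str
    t: np.ndarray                 # (T,)
    est_heading: np.ndarray       # (B, T) radians, NaN where undecodable
    confidence: np.ndarray        # (B, T)
    W_final: np.ndarray | None    # (B, 18, 81) or None
    corr_t: np.ndarray | None     # (K,) times of correlation samples
    weight_corr: np.ndarray | None  # (B, K) correlation with W_optimal
    spike_count: np.ndarray       # (B, 141) total spikes per neuron
    comm_spike_fanout: np.ndarray  # (B,) accumulated spike-fanout count
    n_steps: int
    epg_trace: np.ndarray | None = None   # (B, T, 18) if recorded
    spikes: np.ndarray | None = None      # (B, T, 141) bool if recorded


class HeadingModel:
    """Connectivity-constrained ring-attractor heading estimator.

    Parameters
    ----------
    world : World
        Landmark layout and field of view.
    trajectory : Trajectory
        Ground-truth pose record driving the inputs.
    config : ModelConfig, optional
        Circuit parameters.
    sensor_table : DataFrame, optional
        Recorded sensor stream (columns t, bearing_landmark1..K,
        angular_velocity).  When given, the measured bearings and angular
        velocity replace the ground-truth-derived ones (the trajectory is
        still used as evaluation truth), and no fresh measurement noise is
        added to the recorded angular velocity.
    """

    def __init__(
        self,
        world: World,
        trajectory: Trajectory,
        config: ModelConfig | None = None,
        sensor_table: pd.DataFrame | None = None,
    ):
        self.world = world
        self.trajectory = trajectory
        self.config = config or ModelConfig()
        self.layout = net.build_layout()
        self.connectome = net.build_connectome(self.layout)
        self.sensor_table = sensor_table
        self._W_opt_cache: np.ndarray | None = None

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_dataframes(
        cls,
        world_df: pd.DataFrame,
        trajectory_df: pd.DataFrame,
        config: ModelConfig | None = None,
        fov: float = 270.0,
    ) -> "HeadingModel":
        return cls(
            World.from_frame(world_df, fov=fov),
            Trajectory.from_frame(trajectory_df),
            config=config,
        )

    # -- input precomputation --------------------------------------------

    def _bearing_series(self) -> np.ndarray:
        """(T, K) egocentric bearings in degrees, NaN where undetected."""
        if self.sensor_table is not None:
            cols = [
                f"bearing_landmark{k + 1}" for k in range(self.world.n_landmarks)
            ]
            b = self.sensor_table[cols].to_numpy(dtype=float)
            if len(b) != len(self.trajectory):
                raise ValueError("sensor table length must match trajectory")
            return b
        b = trajectory_bearings(self.world, self.trajectory)
        visible = np.abs(b) <= self.world.fov / 2.0
        return np.where(visible, b, np.nan)

    def _ring_activation01(self) -> np.ndarray:
        """(T, 81) normalized analytic ring activation in [0, 1]."""
        bank01 = replace(self.config.bank, peak_current=1.0)
        return ring_drive(self._bearing_series(), bank01)

    def _measured_av(self, rng: np.random.Generator, n_batch: int) -> np.ndarray:
        """(B, T) angular-velocity measurement driving P-EN."""
        T = len(self.trajectory)
        if self.sensor_table is not None:
            av = self.sensor_table["angular_velocity"].to_numpy(dtype=float)
            return np.broadcast_to(av, (n_batch, T)).copy()
        av = self.trajectory.angular_velocity
        return av[None, :] + rng.standard_normal((n_batch, T)) * self.config.noise.av_sigma

    # -- offline solution --------------------------------------------------

    def optimize_weights(
        self, subsample: int = 10, return_info: bool = False
    ):
        """Offline optimal weights: positive-lasso fit of target compass
        activity on the analytic ring activation along this trajectory,
        sign-flipped and scaled.  Deterministic; cached."""
        if self._W_opt_cache is None or return_info:
            r01 = self._ring_activation01()[::subsample]
            r_hz = self.config.ring_rate_max * r01
            c_target = plast.target_compass_activity(
                self.trajectory.heading[::subsample],
                self.layout.preferred_angles,
                amplitude=self.config.offline.target_amplitude,
                sigma=self.config.offline.target_sigma,
            )
            W, info = plast.optimize_weights_offline(
                r_hz, c_target, self.config.offline
            )
            self._W_opt_cache = W
            if return_info:
                return W, info
        return self._W_opt_cache

    # -- the simulation core ----------------------------------------------

    def fit(
        self,
        configuration: str = "online",
        rule: str = "hebbian",
        seed: int = 0,
        n_seeds: int = 1,
        W_init: np.ndarray | None = None,
        record_confidence: bool = True,
        record_traces: bool = False,
        record_spikes: bool = False,
    ) -> "HeadingResults":
        """Run the spiking simulation and return fitted results.

        configuration: 'optimal' (fixed offline-solved weights), 'online'
        (plastic weights, learned by ``rule`` from random initialization),
        or 'av_only' (all ring->E-PG weights zero).
        """
        if configuration not in CONFIGURATIONS:
            raise ValueError(f"configuration must be one of {CONFIGURATIONS}")
        if rule not in ("hebbian", "errmin"):
            raise ValueError("rule must be 'hebbian' or 'errmin'")
        cfg = self.config
        traj = self.trajectory
        T = len(traj)
        B = n_seeds
        master = np.random.SeedSequence(seed)
        rng = np.random.default_rng(master)

        W_opt = self.optimize_weights() if configuration != "av_only" else None
        if configuration == "optimal":
            W = np.broadcast_to(W_opt, (B, 18, 81)).copy()
            learning = False
        elif configuration == "online":
            if W_init is None:
                W = plast.random_init_weights(
                    rng, scale=cfg.hebbian.b, shape=(B, 18, 81)
                )
            else:
                W = np.broadcast_to(W_init, (B, 18, 81)).astype(float).copy()
            learning = True
            if W_opt is None:
                W_opt = self.optimize_weights()
        else:  # av_only
            W = None
            learning = False

        r01_series = self._ring_activation01()          # (T, 81)
        av_meas = self._measured_av(rng, B)             # (B, T)
        ring_spiking = cfg.ring_mode == "spiking"
        ring_currents = None
        if ring_spiking:
            scale = cfg.bank.peak_current
            ring_currents = scale * r01_series

        state = net.NetworkState.zeros(B)
        net.init_bump(
            state, float(traj.heading[0]), self.layout, self.connectome,
            cfg.lif, rng, epg_bias=cfg.epg_bias,
        )

        est = np.empty((B, T))
        conf = np.empty((B, T)) if record_confidence else None
        trace_rec = np.empty((B, T, 18)) if record_traces else None
        spike_rec = np.zeros((B, T, net.N_TOTAL), dtype=bool) if record_spikes else None
        theta = self.layout.preferred_angles
        dec_w = self.layout.decoder_weights
        cos_t, sin_t = dec_w * np.cos(theta), dec_w * np.sin(theta)
        spike_count = np.zeros((B, net.N_TOTAL))
        fanout = self.connectome.mask().sum(axis=1).astype(float)
        if configuration != "av_only":
            fanout = fanout.copy()
            fanout[self.layout.ring] += 18  # plastic ring->E-PG edges
        comm_acc = np.zeros(B)

        corr_every = max(1, int(round(cfg.corr_sample_dt / cfg.lif.dt)))
        corr_t, corr_vals = [], []

        zeros_vis = np.zeros((B, 81))
        epg_sl = self.layout.epg
        for t_i in range(T):
            av_dr = pen_drive(av_meas[:, t_i], cfg.av_enc)  # (B, 16)
            if ring_spiking:
                vis = np.broadcast_to(ring_currents[t_i], (B, 81))
                r_hz = state.trace[:, self.layout.ring]
            else:
                vis = zeros_vis
                r_hz = np.broadcast_to(
                    cfg.ring_rate_max * r01_series[t_i], (B, 81)
                )
            net.step_network(
                state, vis, av_dr, W if W is not None else None,
                cfg.vis_gain * r_hz if W is not None else None,
                self.connectome, self.layout, cfg.lif, rng,
                epg_bias=cfg.epg_bias,
            )
            c_hz = state.trace[:, epg_sl]
            if learning and (t_i % cfg.learn_every == 0):
                r_gate = r_hz / cfg.ring_rate_max
                dt_eff = cfg.learn_every * cfg.lif.dt * cfg.learn_gain
                if rule == "hebbian":
                    W = plast.hebbian_update(W, r_gate, c_hz, cfg.hebbian, dt=dt_eff)
                else:
                    W = plast.errmin_update(W, r_gate, c_hz, cfg.errmin, dt=dt_eff)
            # population-vector decode on the E-PG trace
            x = c_hz @ cos_t
            y = c_hz @ sin_t
            tot = c_hz @ dec_w
            est[:, t_i] = np.where(tot > 0, np.arctan2(y, x), np.nan)
            if record_confidence:
                conf[:, t_i] = np.where(tot > 0, np.hypot(x, y) / np.maximum(tot, 1e-300), 0.0)
            spike_count += state.spikes
            comm_acc += state.spikes.astype(float) @ fanout
            if record_traces:
                trace_rec[:, t_i] = c_hz
            if record_spikes:
                spike_rec[:, t_i] = state.spikes
            if learning and (t_i % corr_every == corr_every - 1):
                corr_t.append(traj.t[t_i])
                try:
                    corr_vals.append(readout.weight_correlation(W, W_opt))
                except ValueError:
                    # fully clipped (constant) weights: correlation undefined
                    corr_vals.append(np.full(B, np.nan))

        run = SimulationRun(
            configuration=configuration,
            t=traj.t,
            est_heading=est,
            confidence=conf,
            W_final=W,
            corr_t=np.array(corr_t) if corr_t else None,
            weight_corr=np.stack(corr_vals, axis=1) if corr_vals else None,
            spike_count=spike_count,
            comm_spike_fanout=comm_acc,
            n_steps=T,
            epg_trace=trace_rec,
            spikes=spike_rec,
        )
        return HeadingResults(self, run, rule=rule, seed=seed)


class HeadingResults:
    """Fit results: decoded heading, error metrics, learned weights.

    Per-seed metrics are computed lazily from the raw batched run.
    """

    def __init__(self, model: HeadingModel, run: SimulationRun, rule: str, seed: int):
        self.model = model
        self.run = run
        self.rule = rule
        self.seed = seed

    # -- basic accessors ---------------------------------------------------

    @property
    def configuration(self) -> str:
        return self.run.configuration

    @property
    def n_seeds(self) -> int:
        return self.run.est_heading.shape[0]

    @property
    def est_heading(self) -> np.ndarray:
        return self.run.est_heading

    @property
    def weights(self) -> np.ndarray | None:
        return self.run.W_final

    # -- metrics -----------------------------------------------------------

    def orientation_rmse(self, wrapped: bool = True) -> np.ndarray:
        """(B,) per-seed orientation RMSE in radians."""
        truth = self.model.trajectory.heading
        if wrapped:
            return np.atleast_1d(readout.circular_rmse(self.run.est_heading, truth))
        return np.atleast_1d(readout.unwrapped_rmse(self.run.est_heading, truth))

    def integrated_positions(self) -> np.ndarray:
        """(B, T, 2) dead-reckoned positions from decoded heading and the
        known ground-truth linear speed."""
        traj = self.model.trajectory
        h = self.run.est_heading
        h = np.where(np.isnan(h), 0.0, h)
        return readout.path_integrate(
            h, traj.linear_speed, traj.dt, origin=traj.position[0]
        )

    def position_error_pct(self) -> np.ndarray:
        """(B,) mean position error as % of ground-truth path length."""
        traj = self.model.trajectory
        return np.atleast_1d(
            readout.position_error_pct(self.integrated_positions(), traj.position)
        )

    def final_weight_correlation(self) -> np.ndarray | None:
        """(B,) correlation of the final learned weights with the offline
        optimum (online configuration only)."""
        if self.run.W_final is None or self.configuration != "online":
            return None
        return np.atleast_1d(
            readout.weight_correlation(self.run.W_final, self.model.optimize_weights())
        )

    def weight_correlation_series(self):
        """(times, (B, K) correlations) during learning, or None."""
        if self.run.weight_corr is None:
            return None
        return self.run.corr_t, self.run.weight_corr

    def abs_error_series(self) -> np.ndarray:
        """(B, T) wrapped absolute orientation error over time."""
        truth = self.model.trajectory.heading
        return np.abs(wrap_rad(self.run.est_heading - truth))

    def estimate_power(self, constants=None):
        """Neuromorphic power estimate for this run: exact neuron-update
        and plasticity terms plus the measured spike-communication term
        (averaged over seeds)."""
        from .power import (
            EnergyConstants,
            comm_power_from_counts,
            neuron_power,
            plasticity_power,
            total_power,
        )

        k = constants or EnergyConstants()
        neuron = neuron_power(net.N_TOTAL, k)
        comm = comm_power_from_counts(
            float(self.run.comm_spike_fanout.mean()), self.run.n_steps, k
        )
        plast_uw = plasticity_power(18 * 81, k)
        return total_power(neuron, comm, plast_uw)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        rmse = self.orientation_rmse()
        lines = [
            "Ring-attractor heading estimation results",
            "=" * 45,
            f"configuration:        {self.configuration}"
            + (f" (rule={self.rule})" if self.configuration == "online" else ""),
            f"seeds:                {self.n_seeds}",
            f"trial duration:       {self.model.trajectory.duration:.1f} s "
            f"({self.run.n_steps} steps at {self.model.config.lif.dt*1e3:.0f} ms)",
            f"orientation RMSE:     {rmse.mean():.3f} rad"
            + (f" (sd {rmse.std():.3f})" if self.n_seeds > 1 else ""),
        ]
        if self.model.trajectory.path_length() > 0:
            pe = self.position_error_pct()
            lines.append(
                f"position error:       {pe.mean():.2f} % of path length"
            )
        wc = self.final_weight_correlation()
        if wc is not None:
            lines.append(f"weight correlation:   {wc.mean():.3f} (vs offline optimum)")
        mean_conf = float(np.nanmean(self.run.confidence)) if self.run.confidence is not None else float("nan")
        lines.append(f"decoder confidence:   {mean_conf:.3f} (mean resultant length)")
        return "\n".join(lines)

    def plot_heading(self, ax=None, seed_index: int = 0):
        """Decoded vs ground-truth heading for one seed."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        traj = self.model.trajectory
        ax.plot(traj.t, traj.heading, "k-", lw=1, label="ground truth")
        ax.plot(
            self.run.t, self.run.est_heading[seed_index], ".", ms=1,
            label=f"decoded ({self.configuration})",
        )
        ax.set(xlabel="time (s)", ylabel="heading (rad)")
        ax.legend(loc="upper right", fontsize=8)
        return ax


# ---------------------------------------------------------------------------
# Three-configuration experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentConfig:
    """Specification of a multi-seed, three-configuration comparison."""

    world: World
    trajectory: Trajectory
    model: ModelConfig = field(default_factory=ModelConfig)
    n_seeds: int = 50
    rule: str = "hebbian"
    configurations: tuple[str, ...] = CONFIGURATIONS
    n_bootstrap: int = 1000


@dataclass
class RunMetrics:
    """Aggregated experiment metrics.

    Per-configuration per-seed orientation RMSEs and position errors,
    bootstrap 95% intervals on the means, pairwise Mann-Whitney rank-sum
    p-values, and the online weight-correlation trajectory.
    """

    rmse: dict[str, np.ndarray]
    rmse_ci: dict[str, tuple[float, float]]
    position_error: dict[str, np.ndarray]
    position_error_ci: dict[str, tuple[float, float]]
    weight_corr_t: np.ndarray | None
    weight_corr_mean: np.ndarray | None
    weight_corr_final: np.ndarray | None
    p_values: dict[str, float]
    results: dict[str, HeadingResults]

    def rmse_mean(self, configuration: str) -> float:
        return float(self.rmse[configuration].mean())

    def reduction_pct(self, configuration: str, baseline: str = "av_only") -> float:
        """Relative reduction of mean RMSE vs a baseline configuration, %."""
        base = self.rmse_mean(baseline)
        return 100.0 * (base - self.rmse_mean(configuration)) / base

    def position_reduction_pct(self, configuration: str, baseline: str = "av_only") -> float:
        base = float(self.position_error[baseline].mean())
        return 100.0 * (base - float(self.position_error[configuration].mean())) / base

    def to_dict(self) -> dict:
        out: dict = {"rmse": {}, "position_error": {}, "p_values": self.p_values}
        for k, v in self.rmse.items():
            out["rmse"][k] = {
                "mean": float(v.mean()),
                "ci95": list(self.rmse_ci[k]),
                "per_seed": [float(x) for x in v],
            }
        for k, v in self.position_error.items():
            out["position_error"][k] = {
                "mean": float(v.mean()),
                "ci95": list(self.position_error_ci[k]),
            }
        if self.weight_corr_final is not None:
            out["weight_correlation_final_mean"] = float(self.weight_corr_final.mean())
        return out

    def summary(self) -> str:
        lines = [
            "Three-configuration experiment",
            "=" * 60,
            f"{'configuration':<12} {'RMSE (rad)':>12} {'95% CI':>20} {'pos err %':>10}",
        ]
        for k in self.rmse:
            lo, hi = self.rmse_ci[k]
            pe = float(self.position_error[k].mean())
            lines.append(
                f"{k:<12} {self.rmse[k].mean():>12.3f} "
                f"[{lo:>8.3f}, {hi:>8.3f}] {pe:>10.2f}"
            )
        for pair, p in self.p_values.items():
            lines.append(f"Mann-Whitney {pair}: p = {p:.4g}")
        if self.weight_corr_final is not None:
            lines.append(
                f"final weight correlation (online vs optimal): "
                f"{float(self.weight_corr_final.mean()):.3f}"
            )
        return "\n".join(lines)


def run_experiment(cfg: ExperimentConfig, seed: int = 0) -> RunMetrics:
    """Run the three configurations over ``cfg.n_seeds`` seeds each and
    aggregate metrics; fully reproducible from ``seed``."""
    model = HeadingModel(cfg.world, cfg.trajectory, cfg.model)
    sub = np.random.SeedSequence(seed).spawn(len(cfg.configurations) + 1)
    boot_rng = np.random.default_rng(sub[-1])

    results: dict[str, HeadingResults] = {}
    for i, conf in enumerate(cfg.configurations):
        results[conf] = model.fit(
            configuration=conf,
            rule=cfg.rule,
            seed=int(sub[i].generate_state(1)[0] % (2**31)),
            n_seeds=cfg.n_seeds,
        )

    rmse = {k: r.orientation_rmse() for k, r in results.items()}
    if cfg.trajectory.path_length() > 0:
        pos = {k: r.position_error_pct() for k, r in results.items()}
    else:  # rotation-only trial: position error undefined
        pos = {k: np.full(cfg.n_seeds, np.nan) for k in results}
    rmse_ci = {
        k: readout.bootstrap_ci(v, boot_rng, n_resamples=cfg.n_bootstrap)
        for k, v in rmse.items()
    }
    pos_ci = {
        k: readout.bootstrap_ci(v, boot_rng, n_resamples=cfg.n_bootstrap)
        for k, v in pos.items()
    }
    p_values = {}
    keys = list(rmse)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a, b = keys[i], keys[j]
            p_values[f"{a}_vs_{b}"] = float(
                stats.mannwhitneyu(rmse[a], rmse[b], alternative="two-sided").pvalue
            )

    corr_t = corr_mean = corr_final = None
    if "online" in results:
        series = results["online"].weight_correlation_series()
        if series is not None:
            corr_t, corr = series
            corr_mean = corr.mean(axis=0)
        corr_final = results["online"].final_weight_correlation()

    return RunMetrics(
        rmse=rmse,
        rmse_ci=rmse_ci,
        position_error=pos,
        position_error_ci=pos_ci,
        weight_corr_t=corr_t,
        weight_corr_mean=corr_mean,
        weight_corr_final=corr_final,
        p_values=p_values,
        results=results,
    )
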