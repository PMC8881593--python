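"""Sensory encoding: landmark bearings -> ring-neuron drive, angular
velocity -> P-EN drive, and the trial noise models.

Ring neurons: 27 per landmark, Gaussian receptive fields (sigma 6.44 deg)
with centres spaced 10 deg across a 270 deg field of view.  A landmark
outside the FOV silences its whole sub-population.

P-EN neurons: 8 per hemisphere; the right hemisphere encodes positive
angular velocity, the left negative, linearly up to a saturation speed of
10 rad/s at which the steady-state LIF firing rate is 250 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import LIFParams, lif_current_for_rate_discrete

__all__ = [
    "RingTuningBank",
    "AngularVelocityEncoder",
    "NoiseModel",
    "ring_drive",
    "pen_drive",
    "add_av_noise",
    "load_sensor_table",
    "sensor_table_from_trajectory",
]


@dataclass(frozen=True)
class RingTuningBank:
    """Gaussian receptive-field bank for the 81 ring neurons.

    ``centers`` are 27 bearing angles (degrees) spaced 10 deg, spanning the
    270 deg FOV symmetrically (-130 .. +130); identical for each of the
    three landmark sub-populations.  ``peak_current`` is the input current
    at a receptive-field centre, calibrated so ring neurons fire well into
    their dynamic range without saturating (free scalar; the circuit
    carries no physical current units).
    """

    n_landmarks: int = 3
    neurons_per_landmark: int = 27
    fov: float = 270.0
    spacing: float = 10.0
    sigma: float = 6.44
    peak_current: float = 2.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def centers(self) -> np.ndarray:
        k = self.neurons_per_landmark
        half = (k - 1) / 2.0 * self.spacing  # 130 deg for 27 @ 10 deg
        return np.linspace(-half, half, k)

    @property
    def n_channels(self) -> int:
        return self.n_landmarks * self.neurons_per_landmark


def ring_drive(bearings: np.ndarray, bank: RingTuningBank) -> np.ndarray:
    """Input currents for the 81 ring channels from per-landmark bearings.

    ``bearings``: (..., n_landmarks) egocentric bearings in degrees; NaN
    marks a landmark that is not detected (out of FOV or dropped frame)
    and zeroes its 27-channel sub-population.  Channels are ordered
    landmark-major: landmark k occupies channels [27k, 27k+27).
    """
    b = np.asarray(bearings, dtype=float)
    if b.shape[-1] != bank.n_landmarks:
        raise ValueError(
            f"expected {bank.n_landmarks} bearings, got shape {b.shape}"
        )
    visible = np.isfinite(b) & (np.abs(b) <= bank.fov / 2.0)
    dev = b[..., :, None] - bank.centers  # (..., K, 27)
    act = bank.peak_current * np.exp(-0.5 * (dev / bank.sigma) ** 2)
    act = np.where(visible[..., :, None], act, 0.0)
    return act.reshape(*b.shape[:-1], bank.n_channels)


@dataclass(frozen=True)
class AngularVelocityEncoder:
    """Linear-then-saturating angular-velocity encoding into P-EN currents.

    The drive current is ``baseline_current + gain * clamp(|av|, 0,
    saturation_speed)`` on the hemisphere matching the sign of the
    velocity (right = positive), and ``baseline_current`` alone on the
    other.  The baseline keeps both hemispheres' P-EN active so that slow
    rotations act differentially instead of through a firing threshold
    (a zero baseline leaves the bump pinned at low speeds).  ``gain`` is
    calibrated so the steady-state LIF rate at saturation is
    ``target_peak_rate`` (250 Hz at 10 rad/s).
    """

    n_per_hemisphere: int = 8
    saturation_speed: float = 10.0
    target_peak_rate: float = 250.0
    baseline_current: float = 0.9
    lif: LIFParams = field(default_factory=LIFParams)

    @property
    def gain(self) -> float:
        """Current per rad/s so that baseline + gain * saturation_speed
        drives a simulated LIF neuron at the target peak rate."""
        return (
            lif_current_for_rate_discrete(self.target_peak_rate, self.lif)
            - self.baseline_current
        ) / self.saturation_speed


def pen_drive(angular_velocity, enc: AngularVelocityEncoder) -> np.ndarray:
    """(..., 16) P-EN input currents: first 8 channels right hemisphere
    (positive velocities), last 8 left (negative)."""
    av = np.asarray(angular_velocity, dtype=float)
    if not np.all(np.isfinite(av)):
        raise ValueError("angular velocity must be finite")
    pos = enc.baseline_current + enc.gain * np.clip(av, 0.0, enc.saturation_speed)
    neg = enc.baseline_current + enc.gain * np.clip(-av, 0.0, enc.saturation_speed)
    n = enc.n_per_hemisphere
    out = np.empty(av.shape + (2 * n,))
    out[..., :n] = pos[..., None]
    out[..., n:] = neg[..., None]
    return out


@dataclass(frozen=True)
class NoiseModel:
    """Trial noise: Gaussian angular-velocity measurement noise (rad/s)
    and Gaussian state noise on P-EG/PIntr input currents."""

    av_sigma: float = 0.1
    state_noise_sigma: float = 0.1

    def __post_init__(self):
        if self.av_sigma < 0 or self.state_noise_sigma < 0:
            raise ValueError("noise sigmas must be non-negative")


def add_av_noise(av, noise: NoiseModel, rng: np.random.Generator):
    """Corrupt angular velocity with zero-mean Gaussian measurement noise."""
    av = np.asarray(av, dtype=float)
    if noise.av_sigma == 0.0:
        return av if av.ndim else float(av)
    out = av + rng.standard_normal(av.shape) * noise.av_sigma
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Recorded sensor streams
# ---------------------------------------------------------------------------

def load_sensor_table(path, n_landmarks: int = 3) -> pd.DataFrame:
    """Read a recorded sensor stream: columns ``t``,
    ``bearing_landmark1..K`` (degrees; blank = landmark not detected in
    that frame, emulating frame dropout) and ``angular_velocity`` (rad/s).
    Undetected bearings come back as NaN, which :func:`ring_drive` maps to
    zero drive."""
    df = pd.read_csv(path)
    cols = ["t"] + [f"bearing_landmark{k + 1}" for k in range(n_landmarks)] + [
        "angular_velocity"
    ]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"sensor table missing columns: {missing}")
    return df[cols]


def sensor_table_from_trajectory(
    world, traj, noise: NoiseModel, rng: np.random.Generator,
    dropout_prob: float = 0.0,
) -> pd.DataFrame:
    """Build a synthetic recorded sensor stream from ground truth: noisy
    angular velocity plus per-frame landmark bearings, with optional
    i.i.d. frame dropout blanking all bearings of a frame."""
    from .environment import trajectory_bearings

    bearings = trajectory_bearings(world, traj)
    visible = np.abs(bearings) <= world.fov / 2.0
    bearings = np.where(visible, bearings, np.nan)
    if dropout_prob > 0.0:
        dropped = rng.random(len(traj)) < dropout_prob
        bearings[dropped, :] = np.nan
    av = add_av_noise(traj.angular_velocity, noise, rng)
    data = {"t": traj.t}
    for k in range(world.n_landmarks):
        data[f"bearing_landmark{k + 1}"] = bearings[:, k]
    data["angular_velocity"] = av
    return pd.DataFrame(data)
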