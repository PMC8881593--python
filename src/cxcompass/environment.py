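"""Synthetic worlds, ground-truth trajectories, and egocentric landmark bearings.

A :class:`World` is a small set of point landmarks with a limited field of
view; a :class:`Trajectory` is a uniformly sampled ground-truth pose record
(position, heading, angular velocity, linear speed).  Bearings are computed
egocentrically -- the heading-direction circuit only ever sees where a
landmark sits relative to the agent's own gaze.

Conventions (package-wide): headings in radians, counter-clockwise
positive, 0 = +x axis, wrapped to (-pi, pi].  Bearings and the field of
view in degrees; the FOV is centred on the heading and symmetric, so a
270 deg FOV spans bearings [-135, +135].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._angles import wrap_deg, wrap_rad

__all__ = [
    "Landmark",
    "World",
    "Trajectory",
    "make_rotation_trajectory",
    "make_translation_trajectory",
    "make_parametric_trajectory",
    "landmark_bearing",
    "trajectory_bearings",
    "in_fov",
    "default_rotation_world",
    "default_rotation_trajectory",
    "default_translation_world",
    "default_translation_trajectory",
]


@dataclass(frozen=True)
class Landmark:
    """A point landmark in the world frame (metres)."""

    id: int
    position: tuple[float, float]
    color_tag: str = ""

    def __post_init__(self):
        if not np.all(np.isfinite(self.position)):
            raise ValueError("landmark position must be finite")


@dataclass(frozen=True)
class World:
    """Landmark layout plus the agent's angular field of view.

    Landmark order is meaningful: landmark k drives the k-th ring-neuron
    sub-population.
    """

    landmarks: tuple[Landmark, ...]
    fov: float = 270.0

    def __post_init__(self):
        if not (0.0 < self.fov <= 360.0):
            raise ValueError(f"fov must be in (0, 360], got {self.fov}")
        ids = [lm.id for lm in self.landmarks]
        if len(set(ids)) != len(ids):
            raise ValueError("landmark ids must be unique")
        object.__setattr__(self, "landmarks", tuple(self.landmarks))

    @property
    def n_landmarks(self) -> int:
        return len(self.landmarks)

    def positions(self) -> np.ndarray:
        return np.array([lm.position for lm in self.landmarks], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [lm.id for lm in self.landmarks],
                "x": [lm.position[0] for lm in self.landmarks],
                "y": [lm.position[1] for lm in self.landmarks],
                "color": [lm.color_tag for lm in self.landmarks],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, fov: float = 270.0) -> "World":
        lms = tuple(
            Landmark(int(r.id), (float(r.x), float(r.y)), str(r.color))
            for r in df.itertuples()
        )
        return cls(landmarks=lms, fov=fov)

    @classmethod
    def from_csv(cls, path, fov: float = 270.0) -> "World":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False), fov=fov)


@dataclass
class Trajectory:
    """Uniformly sampled ground-truth pose record.

    Attributes
    ----------
    dt : float
        Sample interval in seconds (default 1 ms).
    t : (T,) array of times, strictly increasing, uniform.
    position : (T, 2) array, metres, world frame.
    heading : (T,) array, radians, wrapped to (-pi, pi].
    angular_velocity : (T,) array, rad/s; heading integrates it.
    linear_speed : (T,) array, m/s, along the heading direction.
    """

    dt: float
    t: np.ndarray
    position: np.ndarray
    heading: np.ndarray
    angular_velocity: np.ndarray
    linear_speed: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.heading = np.asarray(self.heading, dtype=float)
        self.angular_velocity = np.asarray(self.angular_velocity, dtype=float)
        self.linear_speed = np.asarray(self.linear_speed, dtype=float)
        n = len(self.t)
        if not (
            self.position.shape == (n, 2)
            and self.heading.shape == (n,)
            and self.angular_velocity.shape == (n,)
            and self.linear_speed.shape == (n,)
        ):
            raise ValueError("inconsistent trajectory array shapes")
        if n > 1 and not np.allclose(np.diff(self.t), self.dt, rtol=0, atol=1e-9):
            raise ValueError("trajectory sampling must be uniform at dt")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) + self.dt

    def path_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.position, axis=0), axis=1)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "x": self.position[:, 0],
                "y": self.position[:, 1],
                "heading": self.heading,
                "angular_velocity": self.angular_velocity,
                "linear_speed": self.linear_speed,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Trajectory":
        t = df["t"].to_numpy(dtype=float)
        dt = float(t[1] - t[0]) if len(t) > 1 else 1e-3
        return cls(
            dt=dt,
            t=t,
            position=df[["x", "y"]].to_numpy(dtype=float),
            heading=df["heading"].to_numpy(dtype=float),
            angular_velocity=df["angular_velocity"].to_numpy(dtype=float),
            linear_speed=df["linear_speed"].to_numpy(dtype=float),
        )

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        return cls.from_frame(pd.read_csv(path))


def _time_grid(duration: float, dt: float) -> np.ndarray:
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    n = int(round(duration / dt))
    return np.arange(n) * dt


def make_rotation_trajectory(
    duration: float,
    angular_speed_fn: Callable[[np.ndarray], np.ndarray] | float,
    dt: float = 1e-3,
    initial_heading: float = 0.0,
) -> Trajectory:
    """Rotation-only trajectory: agent pinned at the origin, heading
    integrating the given angular-speed profile.
    """
    t = _time_grid(duration, dt)
    if callable(angular_speed_fn):
        av = np.asarray(angular_speed_fn(t), dtype=float) * np.ones_like(t)
    else:
        av = float(angular_speed_fn) * np.ones_like(t)
    heading = wrap_rad(initial_heading + np.concatenate([[0.0], np.cumsum(av[:-1]) * dt]))
    return Trajectory(
        dt=dt,
        t=t,
        position=np.zeros((len(t), 2)),
        heading=heading,
        angular_velocity=av,
        linear_speed=np.zeros_like(t),
    )


def make_translation_trajectory(
    duration: float,
    waypoints: Sequence[Sequence[float]],
    heading_profile: Callable[[np.ndarray], np.ndarray] | None = None,
    dt: float = 1e-3,
) -> Trajectory:
    """Piecewise-linear translation through waypoints at constant speed per
    segment.

    Heading follows ``heading_profile(t)`` when given, otherwise the
    direction of motion of the current segment.  Angular velocity is the
    wrapped forward difference of heading.
    """
    wp = np.asarray(waypoints, dtype=float)
    if wp.ndim != 2 or wp.shape[0] < 2 or wp.shape[1] != 2:
        raise ValueError("need at least two 2-D waypoints")
    seg = np.diff(wp, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    if np.any(seg_len == 0.0):
        raise ValueError("coincident consecutive waypoints (degenerate segment)")
    t = _time_grid(duration, dt)
    total = seg_len.sum()
    # Arc-length parameterization at uniform overall speed.
    s = (t / duration) * total
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    frac = (s - cum[idx]) / seg_len[idx]
    position = wp[idx] + frac[:, None] * seg[idx]
    speed = np.full_like(t, total / duration)
    if heading_profile is not None:
        heading = wrap_rad(np.asarray(heading_profile(t), dtype=float) * np.ones_like(t))
    else:
        heading = wrap_rad(np.arctan2(seg[idx, 1], seg[idx, 0]))
    av = np.empty_like(t)
    av[:-1] = wrap_rad(np.diff(heading)) / dt
    av[-1] = av[-2] if len(t) > 1 else 0.0
    return Trajectory(
        dt=dt, t=t, position=position, heading=heading,
        angular_velocity=av, linear_speed=speed,
    )


def make_parametric_trajectory(
    duration: float,
    position_fn: Callable[[np.ndarray], np.ndarray],
    dt: float = 1e-3,
) -> Trajectory:
    """Smooth trajectory from a parametric position curve.

    Heading is the direction of motion (so path integration of the true
    heading with the true speed reproduces the path), angular velocity the
    wrapped forward difference of heading.
    """
    t = _time_grid(duration, dt)
    position = np.asarray(position_fn(t), dtype=float)
    if position.shape != (len(t), 2):
        raise ValueError("position_fn must return a (T, 2) array")
    vel = np.gradient(position, dt, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    if np.any(speed <= 0):
        raise ValueError("parametric trajectory must keep moving (speed > 0)")
    heading = wrap_rad(np.arctan2(vel[:, 1], vel[:, 0]))
    av = np.empty_like(t)
    av[:-1] = wrap_rad(np.diff(heading)) / dt
    av[-1] = av[-2]
    return Trajectory(
        dt=dt, t=t, position=position, heading=heading,
        angular_velocity=av, linear_speed=speed,
    )


def landmark_bearing(position, heading: float, landmark: Landmark) -> float:
    """Egocentric bearing of a landmark in degrees, wrapped to (-180, 180].

    Positive counter-clockwise; 0 = straight ahead along the heading.
    """
    d = np.asarray(landmark.position, dtype=float) - np.asarray(position, dtype=float)
    if np.hypot(d[0], d[1]) == 0.0:
        raise ValueError("landmark coincides with agent position (degenerate geometry)")
    world_bearing = np.arctan2(d[1], d[0])
    return float(wrap_deg(np.degrees(wrap_rad(world_bearing - heading))))


def trajectory_bearings(world: World, traj: Trajectory) -> np.ndarray:
    """(T, n_landmarks) egocentric bearings in degrees over a trajectory."""
    pos = world.positions()  # (K, 2)
    d = pos[None, :, :] - traj.position[:, None, :]  # (T, K, 2)
    dist = np.hypot(d[..., 0], d[..., 1])
    if np.any(dist == 0.0):
        raise ValueError("trajectory passes through a landmark")
    world_bearing = np.arctan2(d[..., 1], d[..., 0])
    return wrap_deg(np.degrees(wrap_rad(world_bearing - traj.heading[:, None])))


def in_fov(bearing: float, fov: float) -> bool | np.ndarray:
    """Whether a bearing (degrees) falls inside a symmetric, heading-centred
    field of view; inclusive at the boundary."""
    return np.abs(bearing) <= fov / 2.0


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def default_rotation_world() -> World:
    """Three landmarks at 120 deg world-bearing spacing, 10 m out."""
    angles = np.deg2rad([0.0, 120.0, 240.0])
    return World(
        landmarks=tuple(
            Landmark(k, (10.0 * np.cos(a), 10.0 * np.sin(a)), c)
            for k, (a, c) in enumerate(zip(angles, ("green", "yellow", "red")))
        ),
        fov=270.0,
    )


def default_rotation_trajectory(duration: float = 60.0, dt: float = 1e-3) -> Trajectory:
    """Rotation-only trial: sinusoidal angular velocity peaking at +-2 rad/s
    (period 20 s), so the heading sweeps back and forth through several full
    turns over the trial."""
    return make_rotation_trajectory(
        duration, lambda t: 2.0 * np.sin(2.0 * np.pi * t / 20.0), dt=dt
    )


def default_translation_world() -> World:
    """Two distal landmarks (30 m, near-invariant world bearing along the
    path) and one proximal landmark (~2 m, strongly position-dependent)."""
    return World(
        landmarks=(
            Landmark(0, (30.0 * np.cos(np.deg2rad(60.0)), 30.0 * np.sin(np.deg2rad(60.0))), "green"),
            Landmark(1, (30.0 * np.cos(np.deg2rad(195.0)), 30.0 * np.sin(np.deg2rad(195.0))), "yellow"),
            Landmark(2, (1.5, 1.5), "red"),
        ),
        fov=270.0,
    )


def default_translation_trajectory(
    duration: float = 60.0, dt: float = 1e-3, n_loops: int = 3
) -> Trajectory:
    """Translation trial: a smooth figure-eight of ~1 m half-width
    traversed ``n_loops`` times, heading along the direction of motion.
    Three traversals give turn rates up to ~1 rad/s -- the scale a small
    wheeled platform actually turns at while wandering an arena, and
    comparable to the rotation trial's angular-velocity range."""
    omega = 2.0 * np.pi * n_loops / duration

    def pos(t):
        return np.column_stack(
            [np.sin(omega * t), 0.5 * np.sin(2.0 * omega * t)]
        )

    return make_parametric_trajectory(duration, pos, dt=dt)
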