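"""Seeded virtual learner: synthetic IMU streams of a periodic hand motion.

The generator emulates the structure of the taught exercise — a closed,
roughly elliptical hand trajectory in the x–z plane traversed once per
two-second period, with a deliberate slow-down ("pause") at the top of
the curve — and the measurement chain of a wrist-worn MEMS unit:

* the correct-execution class (``c_alpha``) dwells at the top of the
  curve; the typical-error class (``c_beta``) is the same curve with the
  pause removed (constant angular speed);
* per-period amplitude and duration jitter mimic human repetition
  variability (smoothly interpolated so the trajectory stays C¹);
* positions are double-differentiated, gravity is added, and the result
  is rotated into a slowly wobbling sensor frame, matching the
  quaternion convention of :mod:`motiontutor.signals` by construction;
* white accelerometer noise with the configured spectral density
  (default 0.4 mg/√Hz over the Nyquist bandwidth) is added per axis.

Everything is reproducible from the integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConfigurationError
from .signals import DEFAULT_SAMPLE_RATE, G0, MultiSignal, SensorStream, select_signals

CLASS_ALPHA = "c_alpha"
CLASS_BETA = "c_beta"


@dataclass(frozen=True)
class LearnerConfig:
    """Study conditions of one simulated recording."""

    semi_axis_x: float = 0.30  # m, half-width of the closed curve
    semi_axis_z: float = 0.20  # m, half-height
    center: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    period: float = 2.0  # s, motion period
    pause_frac: float = 0.20  # fraction of the period spent in the dwell
    pause_phase: float = 0.25  # curve fraction of the dwell centre (0.25 = top)
    class_mode: str = CLASS_ALPHA
    amplitude_jitter: float = 0.03  # fractional amplitude s.d. per period
    phase_jitter: float = 0.02  # s, period-duration s.d.
    wobble_deg: float = 5.0  # sensor-orientation wobble amplitude
    wobble_freq: float = 0.2  # Hz, wobble rate
    base_quat: Tuple[float, float, float, float] = (0.0, 0.0, 0.0, 1.0)
    noise_density: float = 0.4  # mg/√Hz accelerometer noise density
    sample_rate: float = DEFAULT_SAMPLE_RATE
    duration: float = 10.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period <= 0 or self.duration <= 0:
            raise ConfigurationError("period and duration must be positive")
        if not 0 <= self.pause_frac < 1:
            raise ConfigurationError("pause_frac must lie in [0, 1)")
        if self.noise_density < 0:
            raise ConfigurationError("noise_density must be >= 0")
        if self.class_mode not in (CLASS_ALPHA, CLASS_BETA):
            raise ConfigurationError(f"unknown class_mode {self.class_mode!r}")
        if min(self.semi_axis_x, self.semi_axis_z) <= 0:
            raise ConfigurationError("semi-axes must be positive")

    @property
    def w(self) -> int:
        """Nominal period in samples."""
        return int(round(self.period * self.sample_rate))


# ---------------------------------------------------------------------------
# phase profile


def _pause_speed_profile(pause_frac: float, n_grid: int = 2048) -> np.ndarray:
    """Periodic angular-speed profile with a dwell covering ≈pause_frac of
    the period; constant profile when pause_frac is 0.

    The profile is ε + (½ − ½cos 2πu)^p; the exponent p is solved so the
    slow region (speed < 10% of peak) occupies the requested fraction.
    """
    u = np.arange(n_grid) / n_grid
    if pause_frac <= 0:
        return np.ones(n_grid)
    eps = 0.02

    def dwell(p: float) -> float:
        r = eps + (0.5 - 0.5 * np.cos(2.0 * np.pi * u)) ** p
        return float(np.mean(r < 0.1 * r.max()))

    lo, hi = 0.2, 50.0
    for _ in range(60):  # dwell() is monotone decreasing in p
        mid = 0.5 * (lo + hi)
        if dwell(mid) > pause_frac:
            hi = mid
        else:
            lo = mid
    p = 0.5 * (lo + hi)
    return eps + (0.5 - 0.5 * np.cos(2.0 * np.pi * u)) ** p


def _phase_of_time(cfg: LearnerConfig) -> Tuple[np.ndarray, np.ndarray]:
    """Sampled curve fraction x(t) ∈ [0, 1) and its local period T(t)."""
    n = int(round(cfg.duration * cfg.sample_rate))
    t = np.arange(n) / cfg.sample_rate
    rng = np.random.default_rng(cfg.seed)

    n_periods = int(np.ceil(cfg.duration / cfg.period)) + 2
    durations = cfg.period + rng.normal(0.0, cfg.phase_jitter, size=n_periods)
    durations = np.maximum(durations, 0.5 * cfg.period)
    boundaries = np.concatenate([[0.0], np.cumsum(durations)])
    # smooth local period; linear interpolation keeps u(t) C¹
    mid = 0.5 * (boundaries[:-1] + boundaries[1:])
    T_t = np.interp(t, mid, durations)
    u = np.cumsum(1.0 / (T_t * cfg.sample_rate))  # periods elapsed
    u -= u[0]

    if cfg.class_mode == CLASS_ALPHA and cfg.pause_frac > 0:
        speed = _pause_speed_profile(cfg.pause_frac)
        # time fraction τ ↦ curve fraction x: dτ ∝ dx / speed(x)
        xg = np.arange(speed.size + 1) / speed.size
        tau_of_x = np.concatenate([[0.0], np.cumsum(1.0 / speed)])
        tau_of_x /= tau_of_x[-1]
        x_raw = np.interp(np.mod(u, 1.0), tau_of_x, xg)
    else:
        x_raw = np.mod(u, 1.0)
    # the dwell of the speed profile sits at x_raw = 0; place it at the
    # configured curve fraction (the "upper position" by default)
    x = np.mod(x_raw + cfg.pause_phase, 1.0)
    return x, u, t


def make_trajectory(
    cfg: LearnerConfig,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sampled closed trajectory: (t, positions (n,3), curve fraction x,
    time phase u).

    ``x`` is the normalized position along the curve; ``u`` counts periods
    elapsed in time, so ``(u mod 1)·w + 1`` is the true pattern probe index
    against which phase recovery can be checked (one-period patterns are
    sampled uniformly in time).
    """
    x, u, t = _phase_of_time(cfg)
    rng = np.random.default_rng(cfg.seed + 1)

    n_periods = int(np.ceil(cfg.duration / cfg.period)) + 2
    amp = 1.0 + rng.normal(0.0, cfg.amplitude_jitter, size=n_periods)
    if cfg.amplitude_jitter > 0:
        # smooth (C²) amplitude modulation across period boundaries
        from scipy.interpolate import CubicSpline

        anchors = np.arange(n_periods) * cfg.period
        j = CubicSpline(anchors, amp)(np.clip(t, anchors[0], anchors[-1]))
    else:
        j = np.ones_like(t)

    phi = 2.0 * np.pi * x
    cx, cy, cz = cfg.center
    pos = np.column_stack(
        [
            cx + cfg.semi_axis_x * j * np.cos(phi),
            np.full_like(phi, cy),
            cz + cfg.semi_axis_z * j * np.sin(phi),
        ]
    )
    return t, pos, x, u


# ---------------------------------------------------------------------------
# measurement synthesis


def _wobble_quats(cfg: LearnerConfig, t: np.ndarray) -> np.ndarray:
    """Slowly wobbling orientation around the base attitude (vector-first)."""
    angle = np.deg2rad(cfg.wobble_deg) * np.sin(2.0 * np.pi * cfg.wobble_freq * t)
    axis = np.array([1.0, 1.0, 0.0]) / np.sqrt(2.0)
    wobble = Rotation.from_rotvec(np.outer(angle, axis))
    base = Rotation.from_quat(np.asarray(cfg.base_quat, dtype=float))
    return (wobble * base).as_quat()


def synth_stream(
    t: np.ndarray,
    pos: np.ndarray,
    cfg: LearnerConfig,
    sensor_id: str = "wrist",
) -> SensorStream:
    """Sensor-frame measurement stream for a sampled trajectory.

    Double-differentiates the positions (central differences), adds the
    gravity vector, rotates into the wobbling sensor frame (a = A·a_iner)
    and adds white accelerometer noise of the configured density over the
    Nyquist bandwidth.
    """
    dt = 1.0 / cfg.sample_rate
    vel = np.gradient(pos, dt, axis=0)
    acc = np.gradient(vel, dt, axis=0)
    acc[:, 2] += G0

    quats = _wobble_quats(cfg, t)
    a_sensor = Rotation.from_quat(quats).apply(acc)

    if cfg.noise_density > 0:
        rng = np.random.default_rng(cfg.seed + 2)
        sigma = cfg.noise_density * 1e-3 * G0 * np.sqrt(cfg.sample_rate / 2.0)
        a_sensor = a_sensor + rng.normal(0.0, sigma, size=a_sensor.shape)

    return SensorStream(
        sensor_id=sensor_id,
        accel=a_sensor,
        quats=quats,
        sample_rate=cfg.sample_rate,
    )


def simulate(cfg: LearnerConfig, sensor_id: str = "wrist"):
    """Full simulation: (stream, truth) with the generating trajectory.

    ``truth["probe"]`` is the true pattern probe index per sample.
    """
    t, pos, x, u = make_trajectory(cfg)
    stream = synth_stream(t, pos, cfg, sensor_id=sensor_id)
    truth = {
        "t": t,
        "pos": pos,
        "curve_fraction": x,
        "phase_periods": u,
        "probe": np.mod(u, 1.0) * cfg.w + 1.0,
        "w": cfg.w,
    }
    return stream, truth


# ---------------------------------------------------------------------------
# labelled training material

#: catalogue indices of the single-sensor setup (see signals.catalogue):
#: accel x/z and position x/z of sensor 0.
ACCEL_X, ACCEL_Z = 0, 2
POS_X, POS_Z = 6, 8
DEFAULT_CLASS_K = (ACCEL_X, ACCEL_Z)
DEFAULT_SHAPE_K = (POS_X, POS_Z)


def make_training_set(
    configs: Dict[str, LearnerConfig],
    n_recordings: int,
    seed: int = 0,
    K: Sequence[int] = DEFAULT_CLASS_K,
    fc: float = 5.0,
) -> List[Tuple[MultiSignal, str]]:
    """Seeded labelled recordings, preprocessed into multi-dimensional
    signals, suitable for pattern building and classifier benchmarking."""
    if not configs:
        raise ConfigurationError("at least one class configuration required")
    ss = np.random.SeedSequence(seed)
    out: List[Tuple[MultiSignal, str]] = []
    for label in sorted(configs):
        cfg = configs[label]
        for child in ss.spawn(n_recordings):
            sub = int(child.generate_state(1)[0] % (2**31))
            stream, _ = simulate(replace(cfg, seed=sub))
            S = select_signals([stream], K, fc=fc, period_w=cfg.w)
            out.append((S, label))
    return out
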