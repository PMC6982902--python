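"""Sampled motion-signal types and the inertial preprocessing chain.

A wearable MEMS unit reports triaxial acceleration in its own (rotating)
sensor frame together with its orientation as a unit quaternion relative to
an Earth-fixed ("inertial") frame.  Before any pattern analysis, each
selected acceleration component is (1) rotated into the inertial frame,
(2) stripped of the constant gravity term, (3) low-pass filtered with a
first-order IIR filter, and (4) optionally integrated once (velocity) or
twice (position), with a per-period mean removal that keeps integrals of
periodic signals bounded instead of modelling gyroscope drift.

Conventions (documented, since raw hardware is out of scope):

* quaternions are vector-first ``(vx, vy, vz, k)`` in the Hamilton
  convention; ``quat_to_rotation`` returns the matrix ``A`` that rotates
  inertial-frame vectors into sensor readings, so ``B = A⁻¹ = Aᵀ`` maps a
  sensor-frame acceleration back to the inertial frame;
* gravity appears as ``(0, 0, +9.81) m/s²`` on the inertial z axis for a
  static, upright sensor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Dict, Iterable, Sequence

import numpy as np
from scipy import signal as sps
from scipy.spatial.transform import Rotation

from .errors import (
    CannotSegmentError,
    ConfigurationError,
    InvalidInputError,
    InvalidKindError,
)

G0 = 9.81  # m/s², gravitational acceleration on the inertial z axis
DEFAULT_SAMPLE_RATE = 100.0  # Hz, 10 ms control tick


class Kind(str, Enum):
    ACCEL = "accel"
    VELOCITY = "velocity"
    POSITION = "position"


AXES = ("x", "y", "z")

#: Kind obtained by one rectangular integration.
_INTEGRAL_OF = {Kind.ACCEL: Kind.VELOCITY, Kind.VELOCITY: Kind.POSITION}

#: Physical units per kind (metres-based).
UNITS = {Kind.ACCEL: "m/s^2", Kind.VELOCITY: "m/s", Kind.POSITION: "m"}


@dataclass
class OneDSignal:
    """A uniformly sampled one-dimensional motion signal F_i.

    ``values[k]`` is the (k+1)-th probe; probe indices are 1-based in the
    mathematical notation used throughout the package.
    """

    index: int
    values: np.ndarray
    kind: Kind = Kind.ACCEL
    axis: str = "x"
    frame: str = "inertial"
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise InvalidInputError("signal must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("signal contains non-finite samples")
        if self.axis not in AXES:
            raise InvalidInputError(f"unknown axis {self.axis!r}")
        self.kind = Kind(self.kind)
        if self.sample_rate <= 0:
            raise InvalidInputError("sample_rate must be positive")

    @property
    def m(self) -> int:
        """Number of probes."""
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def units(self) -> str:
        return UNITS[self.kind]


@dataclass
class MultiSignal:
    """The indexed set S = {S_i : i ∈ K} of selected one-dimensional signals."""

    signals: Dict[int, OneDSignal]

    def __post_init__(self) -> None:
        if not self.signals:
            raise ConfigurationError("selection set K must be non-empty")
        lengths = {s.m for s in self.signals.values()}
        rates = {s.sample_rate for s in self.signals.values()}
        if len(lengths) != 1:
            raise InvalidInputError("member signals must share their length")
        if len(rates) != 1:
            raise InvalidInputError("member signals must share their sample rate")
        for i, s in self.signals.items():
            if s.index != i:
                raise ConfigurationError(f"signal index {s.index} filed under key {i}")

    @property
    def K(self) -> tuple:
        return tuple(sorted(self.signals))

    @property
    def m(self) -> int:
        return next(iter(self.signals.values())).m

    @property
    def sample_rate(self) -> float:
        return next(iter(self.signals.values())).sample_rate

    def __getitem__(self, i: int) -> OneDSignal:
        return self.signals[i]

    def window(self, n: int) -> "MultiSignal":
        """The trailing n-sample window of every member."""
        return MultiSignal(
            {i: replace(s, values=s.values[-n:]) for i, s in self.signals.items()}
        )


@dataclass(frozen=True)
class QuaternionSample:
    """Orientation quaternion (vx, vy, vz, k), vector part first."""

    vx: float
    vy: float
    vz: float
    k: float

    def as_array(self) -> np.ndarray:
        return np.array([self.vx, self.vy, self.vz, self.k], dtype=float)

    def normalized(self) -> "QuaternionSample":
        q = self.as_array()
        norm = float(np.linalg.norm(q))
        if not np.isfinite(norm) or norm < 1e-12:
            raise InvalidInputError("quaternion has zero or non-finite norm")
        q /= norm
        return QuaternionSample(*q)


@dataclass(frozen=True)
class RotationMatrix:
    """Orthonormal 3×3 rotation matrix A (sensor attitude)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (3, 3):
            raise InvalidInputError("rotation matrix must be 3x3")
        if not np.allclose(m.T @ m, np.eye(3), atol=1e-9):
            raise InvalidInputError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(m), 1.0, atol=1e-9):
            raise InvalidInputError("rotation matrix determinant is not +1")

    @property
    def inverse(self) -> np.ndarray:
        """B = A⁻¹ = Aᵀ, the sensor→inertial change of coordinates."""
        return self.matrix.T


@dataclass
class SensorStream:
    """Raw per-tick output of one inertial sensor."""

    sensor_id: str
    accel: np.ndarray  # (n, 3) sensor-frame accelerations, m/s²
    quats: np.ndarray  # (n, 4) vector-first unit quaternions
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        self.quats = np.atleast_2d(np.asarray(self.quats, dtype=float))
        if self.accel.shape[1] != 3 or self.quats.shape[1] != 4:
            raise InvalidInputError("accel must be (n,3) and quats (n,4)")
        if self.accel.shape[0] != self.quats.shape[0]:
            raise InvalidInputError("accel and quats must have the same length")

    @property
    def n(self) -> int:
        return self.accel.shape[0]


# ---------------------------------------------------------------------------
# frame handling


def quat_to_rotation(q: QuaternionSample | Sequence[float]) -> RotationMatrix:
    """Rotation matrix A of the sensor for one orientation sample.

    Raises :class:`InvalidInputError` for a zero-norm quaternion.
    """
    if not isinstance(q, QuaternionSample):
        q = QuaternionSample(*np.asarray(q, dtype=float))
    q = q.normalized()
    return RotationMatrix(Rotation.from_quat(q.as_array()).as_matrix())


def to_inertial(a: Sequence[float], A: RotationMatrix) -> np.ndarray:
    """Express a sensor-frame acceleration in the inertial frame: B·a, B = Aᵀ."""
    if not isinstance(A, RotationMatrix):
        A = RotationMatrix(np.asarray(A))
    return A.inverse @ np.asarray(a, dtype=float)


def remove_gravity(a_iner: Sequence[float]) -> np.ndarray:
    """Subtract the constant gravity vector (0, 0, g₀) from an inertial accel."""
    a = np.array(a_iner, dtype=float)
    a[..., 2] -= G0
    return a


# ---------------------------------------------------------------------------
# filtering and integration


def iir_alpha(fc: float, sample_rate: float) -> float:
    """Smoothing coefficient of the first-order IIR low-pass for cutoff fc.

    Standard RC mapping: α = 2π·fc·Δt / (2π·fc·Δt + 1).
    """
    if not 0 < fc < sample_rate / 2:
        raise InvalidInputError("fc must lie in (0, sample_rate/2)")
    x = 2.0 * np.pi * fc / sample_rate
    return x / (x + 1.0)


def iir_lowpass(s: OneDSignal, fc: float) -> OneDSignal:
    """First-order IIR low-pass  o^k = (1−α)·o^{k−1} + α·f^k,  o¹ = f¹.

    Initialising with the first sample avoids the step transient of a
    zero-initialised filter; DC gain is exactly one.
    """
    alpha = iir_alpha(fc, s.sample_rate)
    # lfilter with state chosen so that the first output equals f¹.
    zi = np.array([(1.0 - alpha) * s.values[0]])
    out, _ = sps.lfilter([alpha], [1.0, -(1.0 - alpha)], s.values, zi=zi)
    return replace(s, values=out)


def _detrend_per_period(values: np.ndarray, w: int) -> np.ndarray:
    """Subtract the mean of each consecutive length-w window (trailing partial
    window uses its own mean)."""
    out = values.copy()
    for start in range(0, values.size, w):
        seg = out[start : start + w]
        seg -= seg.mean()
    return out


def integrate(
    s: OneDSignal,
    detrend_per_period: bool = False,
    period_w: int | None = None,
) -> OneDSignal:
    """Rectangular (Euler) cumulative integration of an accel or velocity signal.

    With ``detrend_per_period`` the per-window mean is removed before summing,
    which keeps the integral of a periodic signal bounded without modelling
    sensor drift.  Position signals cannot be integrated further.
    """
    if s.kind not in _INTEGRAL_OF:
        raise InvalidKindError(f"cannot integrate a {s.kind.value} signal")
    vals = s.values
    if detrend_per_period:
        if period_w is None or period_w < 1:
            raise InvalidInputError("detrend_per_period requires period_w >= 1")
        vals = _detrend_per_period(vals, int(period_w))
    out = np.cumsum(vals) * s.dt
    return replace(s, values=out, kind=_INTEGRAL_OF[s.kind])


# ---------------------------------------------------------------------------
# signal selection (the preprocessing chain)


@dataclass(frozen=True)
class SignalSpec:
    """One entry of the signal catalogue: which sensor, kind and axis an
    integer signal index refers to."""

    index: int
    sensor_id: str
    kind: Kind
    axis: str


def catalogue(sensor_ids: Sequence[str]) -> Dict[int, SignalSpec]:
    """Deterministic index catalogue: for the u-th sensor, indices
    9u .. 9u+8 run over kinds (accel, velocity, position) × axes (x, y, z)."""
    cat: Dict[int, SignalSpec] = {}
    for u, sid in enumerate(sensor_ids):
        for ki, kind in enumerate((Kind.ACCEL, Kind.VELOCITY, Kind.POSITION)):
            for ai, axis in enumerate(AXES):
                idx = 9 * u + 3 * ki + ai
                cat[idx] = SignalSpec(idx, sid, kind, axis)
    return cat


def stream_to_inertial(stream: SensorStream) -> np.ndarray:
    """Per-tick motion acceleration in the inertial frame: Aᵀ·a − g."""
    rot = Rotation.from_quat(stream.quats / np.linalg.norm(stream.quats, axis=1, keepdims=True))
    # inv() applies B = Aᵀ to every sample at once
    a_iner = rot.inv().apply(stream.accel)
    return remove_gravity(a_iner)


def select_signals(
    streams: Iterable[SensorStream],
    K: Sequence[int],
    fc: float = 5.0,
    detrend_per_period: bool = True,
    period_w: int | None = None,
) -> MultiSignal:
    """Build the multi-dimensional signal S for the selection set K.

    Runs the full chain per selected index: frame transform → gravity
    removal → IIR low-pass → zero, one or two integrations depending on the
    requested kind.  ``period_w`` (samples) bounds integration drift; when
    omitted and needed, it is estimated from the dominant autocorrelation
    period of the filtered acceleration.
    """
    streams = list(streams)
    if not K:
        raise ConfigurationError("selection set K must be non-empty")
    cat = catalogue([st.sensor_id for st in streams])
    by_id = {st.sensor_id: st for st in streams}

    out: Dict[int, OneDSignal] = {}
    motion_cache: Dict[str, np.ndarray] = {}
    for idx in K:
        if idx not in cat:
            raise ConfigurationError(f"unknown signal index {idx}")
        spec = cat[idx]
        st = by_id[spec.sensor_id]
        if spec.sensor_id not in motion_cache:
            motion_cache[spec.sensor_id] = stream_to_inertial(st)
        a_motion = motion_cache[spec.sensor_id][:, AXES.index(spec.axis)]
        sig = OneDSignal(
            index=idx,
            values=a_motion,
            kind=Kind.ACCEL,
            axis=spec.axis,
            sample_rate=st.sample_rate,
        )
        sig = iir_lowpass(sig, fc)
        n_int = (Kind.ACCEL, Kind.VELOCITY, Kind.POSITION).index(spec.kind)
        if n_int and detrend_per_period and period_w is None:
            period_w = estimate_period(sig.values, sig.sample_rate)
        for _ in range(n_int):
            sig = integrate(sig, detrend_per_period=detrend_per_period, period_w=period_w)
        out[idx] = sig
    return MultiSignal(out)


def estimate_period(
    values: np.ndarray,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    min_lag: int | None = None,
    max_lag: int | None = None,
    threshold: float = 0.3,
) -> int:
    """Dominant period (samples) from the normalized autocorrelation peak.

    The peak is searched in ``[min_lag, max_lag]`` (defaults: 0.2 s to a
    third of the record) and must exceed ``threshold`` of the zero-lag
    value, otherwise :class:`CannotSegmentError` is raised.
    """
    x = np.asarray(values, dtype=float)
    x = x - x.mean()
    n = x.size
    if min_lag is None:
        min_lag = max(2, int(0.2 * sample_rate))
    if max_lag is None:
        max_lag = n // 3
    if max_lag <= min_lag:
        raise CannotSegmentError("record too short for period estimation")
    ac = np.correlate(x, x, mode="full")[n - 1 :]
    if ac[0] <= 0:
        raise CannotSegmentError("signal has no variance")
    # unbiased normalization: the raw estimator tapers as (n−lag)/n, which
    # would favour short lags over the true period
    lags = np.arange(ac.size)
    ac = ac / ac[0] * (n / np.maximum(n - lags, 1))
    band = ac[min_lag : max_lag + 1]
    # the fundamental ties with its multiples: among near-maximal local
    # peaks, take the smallest lag
    peaks, _ = sps.find_peaks(band)
    if peaks.size:
        good = peaks[band[peaks] >= 0.9 * band[peaks].max()]
        peak = int(good.min()) + min_lag
    else:
        peak = int(np.argmax(band)) + min_lag
    if ac[peak] < threshold:
        raise CannotSegmentError(
            f"no autocorrelation peak above {threshold} in the lag band"
        )
    return peak
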