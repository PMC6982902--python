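"""Phase synchronization and motion-error computation.

The teaching loop must know which probe of a one-period pattern
corresponds to "now".  Matching the current signal against a *time*
pattern fits the time-shift parameter b, whose value at k = 0 addresses
the last signal sample — so the fitted b *is* the current pattern probe
(the "time point" τ).  Per-signal candidates are aggregated by a
reliability-weighted circular mean, since τ lives on the period circle.

The motion error is the reliability-gated, recency-weighted average of
the last deviations between each *shape* signal and its shape pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .errors import InvalidInputError, NoSyncError
from .matching import GridAxis, MatchGrid, h_distance, wrap_probe
from .patterns import Pattern1D
from .signals import MultiSignal, OneDSignal

#: default reliability threshold on h over normalized windows
H_MAX = 0.05
#: weight floor so that an exact match (h = 0) keeps a finite weight
_EPS = 1e-9

#: Default grid for time-point estimation.  The time scale is pinned at
#: a = 1: a full-period window containing a dwell (the taught pause) is
#: otherwise ambiguous — a small time-scale change can slide the phase by
#: several probes while the flat dwell absorbs the slack.  Tempo deviations
#: are handled by re-estimating the time point every tick instead.
SYNC_GRID = MatchGrid(
    a=GridAxis(1.0, 1.0, 1),
    b=None,
    b_count=20,
    c=GridAxis(0.8, 1.2, 5),
    d=GridAxis(-0.1, 0.1, 3),
)


@dataclass
class TimePointEstimate:
    """Aggregate time point τ (circular coordinate in [1, w+1)) plus the
    per-signal candidates; probe indices come from rounding τ modulo w."""

    tau: float
    w: int
    candidates: List[Tuple[float, float]]  # (b, h) per contributing signal
    reliable: bool


@dataclass
class ErrorVector:
    """Signed deviations of the shape signals from their patterns."""

    components: np.ndarray
    mapping: Tuple[int, ...]  # component order → shape-pattern index

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.components.size != len(self.mapping):
            raise InvalidInputError("component/mapping length mismatch")

    @property
    def n(self) -> int:
        return self.components.size


def time_point_1d(
    P_time: Pattern1D,
    S_i: OneDSignal,
    grid: MatchGrid | None = None,
    n: int | None = None,
) -> Tuple[float, float]:
    """One signal's (b, h) candidate for the time point."""
    h, res = h_distance(P_time, S_i, grid=grid or SYNC_GRID, n=n)
    b = float(wrap_probe(np.rint(res.b), P_time.w))
    return b, h


def aggregate_time_point(
    candidates: Sequence[Tuple[float, float]],
    w: int,
    n_best: int = 3,
    h_max: float = H_MAX,
) -> TimePointEstimate:
    """Weighted circular mean of the best per-signal time points.

    The ``n_best`` lowest-h candidates enter with weights ∝ 1/(h+ε); the
    estimate is reliable iff the best h is at or below ``h_max``.
    """
    if not candidates:
        raise InvalidInputError("no time-point candidates")
    ranked = sorted(candidates, key=lambda t: t[1])[: max(1, n_best)]
    weights = np.array([1.0 / (h + _EPS) for _, h in ranked])
    angles = 2.0 * np.pi * (np.array([b for b, _ in ranked]) - 1.0) / w
    z = np.sum(weights * np.exp(1j * angles)) / weights.sum()
    ang = float(np.angle(z)) % (2.0 * np.pi)
    tau = 1.0 + ang * w / (2.0 * np.pi)  # circular coordinate in [1, w+1)
    reliable = ranked[0][1] <= h_max
    return TimePointEstimate(tau=tau, w=w, candidates=list(ranked), reliable=reliable)


def shape_index(tau: float, k_offset: int, w: int) -> int:
    """Pattern probe aligned with the signal probe k_offset samples back:
    ind(k) = wrap(round(τ − k_offset))."""
    return int(wrap_probe(np.rint(tau - k_offset), w))


def motion_error(
    shape_patterns: Dict[int, Pattern1D],
    S_cur: MultiSignal,
    tpe: TimePointEstimate,
    n_avg: int = 10,
) -> ErrorVector:
    """Recency-weighted deviation of each shape signal from its pattern.

    Weights rise linearly from 0 at the oldest of the ``n_avg`` samples to
    1 at the newest.  Requires a reliable time point; otherwise the caller
    must skip this tick (:class:`NoSyncError`).
    """
    if not tpe.reliable:
        raise NoSyncError("time point unreliable; skip this tick")
    if n_avg < 1:
        raise InvalidInputError("n_avg must be >= 1")
    mapping = tuple(sorted(shape_patterns))
    ks = np.arange(n_avg)
    weights = np.ones(1) if n_avg == 1 else 1.0 - ks / (n_avg - 1)
    comps = []
    for i in mapping:
        pat = shape_patterns[i]
        sig = S_cur[i]
        if n_avg > sig.m:
            raise InvalidInputError("n_avg exceeds the signal length")
        idx = np.array([shape_index(tpe.tau, int(k), pat.w) for k in ks])
        dev = sig.values[sig.m - 1 - ks] - pat.probes[idx - 1]
        comps.append(float(np.sum(weights * dev) / np.sum(weights)))
    return ErrorVector(components=np.array(comps), mapping=mapping)
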