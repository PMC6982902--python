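"""One-period pattern construction from recorded periodic signals.

A pattern is built from "a dozen to several dozen" repetitions of a
movement: the signal is segmented into one-period windows (dominant
autocorrelation lag, cross-correlation alignment), averaged probe-wise,
and windows lying far (in the h metric) from the running average are
rejected before re-averaging — a one-cluster simplification of k-means
with h as the metric.  Patterns carry *roles* assigned by the expert:

* ``class``  — used by the kNNModel classifier,
* ``time``   — used for phase synchronization (time-point estimation),
* ``shape``  — the reference trajectory against which motion error and
  RMSE are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from . import matching
from .errors import (
    CannotSegmentError,
    ConfigurationError,
    DegenerateInputError,
    InvalidInputError,
)
from .matching import GridAxis, MatchGrid
from .signals import Kind, MultiSignal, OneDSignal, estimate_period

ROLES = frozenset({"class", "time", "shape"})


@dataclass
class Pattern1D:
    """A one-period template P_i = (p¹..p^w)."""

    index: int
    probes: np.ndarray
    roles: frozenset = frozenset()
    kind: Kind = Kind.ACCEL
    axis: str = "x"
    sample_rate: float = 100.0

    def __post_init__(self) -> None:
        self.probes = np.asarray(self.probes, dtype=float)
        if self.probes.size < 2:
            raise InvalidInputError("pattern needs at least 2 probes")
        if not np.all(np.isfinite(self.probes)):
            raise InvalidInputError("pattern contains non-finite probes")
        self.roles = frozenset(self.roles)
        if not self.roles <= ROLES:
            raise InvalidInputError(f"unknown roles {set(self.roles) - ROLES}")
        self.kind = Kind(self.kind)

    @property
    def w(self) -> int:
        return self.probes.size


@dataclass
class PatternMD:
    """Multi-dimensional pattern P_u = {P_{i,u} : i ∈ K}, optionally labelled."""

    members: Dict[int, Pattern1D]
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise InvalidInputError("multi-dimensional pattern must be non-empty")
        for i, p in self.members.items():
            if p.index != i:
                raise ConfigurationError(f"pattern index {p.index} filed under {i}")

    @property
    def K(self) -> tuple:
        return tuple(sorted(self.members))

    def with_role(self, role: str) -> Dict[int, Pattern1D]:
        """Members carrying a role; all members if none is marked."""
        sel = {i: p for i, p in self.members.items() if role in p.roles}
        return sel or dict(self.members)


@dataclass
class PatternBank:
    """Ordered, labelled sequence of multi-dimensional patterns."""

    entries: List[PatternMD]
    label_set: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.entries:
            raise ConfigurationError("pattern bank must hold at least one entry")
        labels = [e.label for e in self.entries]
        if any(l is None for l in labels):
            raise ConfigurationError("banked patterns must be labelled")
        if not self.label_set:
            self.label_set = tuple(dict.fromkeys(labels))
        unknown = set(labels) - set(self.label_set)
        if unknown:
            raise ConfigurationError(f"labels outside the declared set: {unknown}")

    @property
    def n_pairs(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# segmentation


def _align_shift(ref: np.ndarray, win: np.ndarray) -> int:
    """Cyclic shift maximizing the circular cross-correlation with ref."""
    a = ref - ref.mean()
    b = win - win.mean()
    corr = np.fft.irfft(np.fft.rfft(a) * np.conj(np.fft.rfft(b)), n=a.size)
    return int(np.argmax(corr))


def _alignment_score(values: np.ndarray, w: int, max_windows: int = 5) -> float:
    """Mean squared inter-window residual after cyclic alignment.

    The first window is skipped: it carries the filter warm-up transient.
    """
    n_win = min(values.size // w, max_windows)
    if n_win < 3:
        return np.inf
    wins = [values[j * w : (j + 1) * w] for j in range(1, n_win)]
    ref = wins[0]
    return float(
        np.mean(
            [np.mean((np.roll(win, _align_shift(ref, win)) - ref) ** 2) for win in wins[1:]]
        )
    )


def refine_period(values: np.ndarray, w0: int, span: int = 2) -> int:
    """Integer refinement of an autocorrelation period estimate: the
    candidate within ±span whose windows align most consistently wins
    (the raw estimate carries a ±1 estimator bias)."""
    candidates = [w for w in range(w0 - span, w0 + span + 1) if w >= 2]
    scores = [_alignment_score(values, w) for w in candidates]
    return candidates[int(np.argmin(scores))]


def segment_periods(
    s: OneDSignal | np.ndarray,
    w: int | None = None,
    threshold: float = 0.3,
    align: bool = True,
) -> Tuple[int, List[np.ndarray]]:
    """Cut a periodic signal into aligned one-period windows.

    The period ``w`` defaults to the dominant autocorrelation lag; every
    consecutive length-w window is cyclically shifted to best match the
    first one.  Needs at least three full periods.
    """
    values = np.asarray(getattr(s, "values", s), dtype=float)
    rate = getattr(s, "sample_rate", 100.0)
    if w is None:
        w = refine_period(values, estimate_period(values, rate, threshold=threshold))
    w = int(w)
    n_win = values.size // w
    if n_win < 3:
        raise CannotSegmentError(
            f"need >= 3 full periods, found {n_win} of length {w}"
        )
    windows = [values[j * w : (j + 1) * w].copy() for j in range(n_win)]
    if align:
        ref = windows[0]
        windows = [np.roll(win, _align_shift(ref, win)) for win in windows]
    return w, windows


# ---------------------------------------------------------------------------
# pattern construction

#: h grid for window-vs-average distances: windows are already aligned, so
#: time scale and shift are pinned (a=1, b=w) and only a small value
#: scale/offset search remains.
_REJECT_GRID = MatchGrid(
    a=GridAxis(1.0, 1.0, 1),
    b=GridAxis(0.0, 0.0, 1),  # replaced per call with the fixed b=w axis
    c=GridAxis(0.8, 1.2, 5),
    d=GridAxis(-0.1, 0.1, 3),
)


def _window_distance(mean: np.ndarray, win: np.ndarray) -> float:
    w = mean.size
    grid = replace(_REJECT_GRID, b=GridAxis(float(w), float(w), 1))
    h, _ = matching.h_distance(mean, win, grid=grid, n=w)
    return h


def build_pattern(
    windows: Sequence[np.ndarray],
    reject_frac: float = 0.25,
    n_rounds: int = 2,
    index: int = 0,
    roles: Iterable[str] = (),
    kind: Kind = Kind.ACCEL,
    axis: str = "x",
    sample_rate: float = 100.0,
) -> Pattern1D:
    """Average aligned windows into a pattern, rejecting outliers by h.

    Round 1 is the probe-wise mean of all windows; every further round
    drops the ⌈reject_frac·count⌉ windows farthest (h) from the current
    mean and re-averages.  ``reject_frac = 0`` reduces to plain averaging.
    """
    wins = [np.asarray(win, dtype=float) for win in windows]
    if len(wins) < 3:
        raise InvalidInputError("pattern averaging needs at least 3 windows")
    if not 0 <= reject_frac < 0.5:
        raise InvalidInputError("reject_frac must lie in [0, 0.5)")
    if len({win.size for win in wins}) != 1:
        raise InvalidInputError("windows must share their length")

    survivors = list(wins)
    mean = np.mean(survivors, axis=0)
    for _ in range(max(0, n_rounds - 1)):
        n_drop = math.ceil(reject_frac * len(survivors))
        if n_drop == 0:
            continue
        if n_drop >= len(survivors):
            raise DegenerateInputError("rejection budget would drop every window")
        dists = np.array([_window_distance(mean, win) for win in survivors])
        keep = np.argsort(dists, kind="stable")[: len(survivors) - n_drop]
        survivors = [survivors[j] for j in sorted(keep)]
        mean = np.mean(survivors, axis=0)

    return Pattern1D(
        index=index,
        probes=mean,
        roles=frozenset(roles),
        kind=kind,
        axis=axis,
        sample_rate=sample_rate,
    )


def build_pattern_md(
    S: MultiSignal,
    roles: Dict[int, Iterable[str]] | None = None,
    label: str | None = None,
    reject_frac: float = 0.25,
    n_rounds: int = 2,
    period_tol: float = 0.05,
) -> PatternMD:
    """Build one pattern per member signal with a common period.

    Per-member period estimates must agree within ``period_tol`` of their
    median; the shared period is the (rounded) median estimate.
    """
    est = {}
    for i, sig in S.signals.items():
        est[i] = refine_period(sig.values, estimate_period(sig.values, sig.sample_rate))
    w_med = float(np.median(list(est.values())))
    for i, wi in est.items():
        if abs(wi - w_med) > period_tol * w_med:
            raise CannotSegmentError(
                f"signal {i} period {wi} inconsistent with median {w_med:.1f}"
            )
    w = int(round(w_med))

    members: Dict[int, Pattern1D] = {}
    for i, sig in S.signals.items():
        _, wins = segment_periods(sig, w=w)
        members[i] = build_pattern(
            wins,
            reject_frac=reject_frac,
            n_rounds=n_rounds,
            index=i,
            roles=(roles or {}).get(i, ()),
            kind=sig.kind,
            axis=sig.axis,
            sample_rate=sig.sample_rate,
        )
    return PatternMD(members=members, label=label)


def edit_pattern(
    P: Pattern1D,
    value_scale: float = 1.0,
    value_offset: float = 0.0,
    resample_w: int | None = None,
) -> Pattern1D:
    """Expert editing: affine value transform plus linear resampling.

    Lets the teacher adapt a pattern to a learner (e.g. scale the amplitude
    to limb length) or change its probe count.
    """
    if value_scale == 0:
        raise InvalidInputError("value_scale must be non-zero")
    probes = P.probes * value_scale + value_offset
    if resample_w is not None:
        if resample_w < 2:
            raise InvalidInputError("resample_w must be >= 2")
        old = np.linspace(0.0, 1.0, P.w)
        new = np.linspace(0.0, 1.0, int(resample_w))
        probes = np.interp(new, old, probes)
    return replace(P, probes=probes)
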