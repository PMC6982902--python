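"""Vibrotactile actuation: actuator algebra, Cα/Cβ algorithms, dispatcher.

Each actuator is a band of four directional vibration units on a plane p
perpendicular to a limb axis.  Per control tick the motion-error vector e
is mapped to a per-actuator 3-vector gᵢ = C·e (inertial frame), rotated
into the actuator's local frame wᵢ = A·gᵢ using the linked sensor's
attitude, and projected onto the unit plane oᵢ = G·wᵢ; the direction of
oᵢ selects the unit to pulse.

Two teaching algorithms consume these vectors:

* **Cα** (fine corrections): a discrete regulator that, once per motion
  period, pulses the unit of the actuator whose |oᵢ| peaked over the
  period — but only if the peak exceeds ``len`` (0.03 m), at least
  ``elaps`` (2.5 s) passed since the previous pulse, and the limb is
  currently outside the taught closed trajectory *moving outward*
  (radial error and radial velocity both positive), so the learner can
  treat the cue as a virtual outer boundary.
* **Cβ** (gross timing errors): pulses a teacher-chosen unit when the
  time point crosses a configured pattern probe, provided the phase
  estimate is reliable.

``teach_step`` is the 10 ms tick of the whole loop: synchronize,
(re-)classify once per period with a two-decision hysteresis, and route
to the algorithm of the current class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .classification import ClassDecision, classify_knn
from .errors import ConfigurationError, InvalidInputError
from .matching import MatchGrid
from .patterns import Pattern1D, PatternBank
from .signals import MultiSignal, RotationMatrix
from .synchronization import (
    ErrorVector,
    TimePointEstimate,
    aggregate_time_point,
    motion_error,
    time_point_1d,
)

LEN_THRESHOLD = 0.03  # m, minimum actuator-vector peak that earns a pulse
ELAPS = 2.5  # s, minimum spacing between activations


@dataclass(frozen=True)
class PulseSpec:
    """Drive waveform metadata of one activation."""

    count: int = 2
    duration_s: float = 0.25
    frequency_hz: float = 20.0


@dataclass(frozen=True)
class ActuatorConfig:
    actuator_id: str
    C: np.ndarray  # (3, n) error-vector weights
    G: np.ndarray  # (2, 3) plane projection (may embed an in-plane rotation)
    linked_sensor: str = ""
    unit_directions: Tuple[float, ...] = (0.0, 90.0, 180.0, 270.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "C", np.atleast_2d(np.asarray(self.C, float)))
        object.__setattr__(self, "G", np.atleast_2d(np.asarray(self.G, float)))
        if self.C.shape[0] != 3:
            raise ConfigurationError("C must have 3 rows")
        if self.G.shape != (2, 3):
            raise ConfigurationError("G must be 2x3")
        if np.linalg.matrix_rank(self.G) < 2:
            raise ConfigurationError("G rows must be independent")

    @property
    def unit_count(self) -> int:
        return len(self.unit_directions)


@dataclass(frozen=True)
class ActuatorCommand:
    actuator_id: str
    unit_id: int
    t: float
    pulse: PulseSpec = PulseSpec()


@dataclass
class BetaTrigger:
    """Teacher-configured Cβ activation: which unit fires at which probe."""

    actuator_id: str
    unit_id: int
    trigger_probe: int
    min_spacing: float = ELAPS  # s; may be set below the period


@dataclass
class TeachState:
    """Mutable per-session state of the teaching loop."""

    len_threshold: float = LEN_THRESHOLD
    elaps: float = ELAPS
    last_activation: Dict[str, float] = field(default_factory=dict)
    period_peak: Dict[str, Tuple[float, np.ndarray]] = field(default_factory=dict)
    last_tau: Optional[float] = None
    beta_last_tau: Optional[float] = None
    current_label: Optional[str] = None
    pending_label: Optional[str] = None
    pending_count: int = 0
    last_decision: Optional[ClassDecision] = None
    centroid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.len_threshold <= 0 or self.elaps <= 0:
            raise InvalidInputError("len and elaps thresholds must be positive")


# ---------------------------------------------------------------------------
# actuator-vector algebra


def actuator_vector(C: np.ndarray, e: ErrorVector | np.ndarray) -> np.ndarray:
    """gᵢ = C·e in the inertial frame."""
    C = np.atleast_2d(np.asarray(C, float))
    ev = e.components if isinstance(e, ErrorVector) else np.asarray(e, float)
    if C.shape[1] != ev.size:
        raise ConfigurationError(
            f"C has {C.shape[1]} columns but the error vector has {ev.size}"
        )
    return C @ ev


def to_actuator_frame(A: RotationMatrix, g_i: np.ndarray) -> np.ndarray:
    """wᵢ = A·gᵢ, the actuator vector in the linked sensor's local frame."""
    if not isinstance(A, RotationMatrix):
        A = RotationMatrix(np.asarray(A))
    return A.matrix @ np.asarray(g_i, float)


def project_to_plane(G: np.ndarray, w_i: np.ndarray) -> np.ndarray:
    """oᵢ = G·wᵢ, the two-dimensional actuator vector on the unit plane."""
    return np.atleast_2d(np.asarray(G, float)) @ np.asarray(w_i, float)


def select_unit(
    o_i: np.ndarray, unit_directions: Sequence[float] = (0.0, 90.0, 180.0, 270.0)
) -> int:
    """Unit whose direction is angularly nearest to oᵢ; ties take the
    lower unit id.  A zero vector carries no direction."""
    o = np.asarray(o_i, float)
    norm = float(np.hypot(o[0], o[1]))
    if norm == 0.0:
        raise InvalidInputError("zero actuator vector has no direction")
    ang = np.degrees(np.arctan2(o[1], o[0]))
    diffs = [abs((ang - d + 180.0) % 360.0 - 180.0) for d in unit_directions]
    return int(np.argmin(diffs))


def _compute_o(
    cfg: ActuatorConfig,
    e: ErrorVector | np.ndarray,
    rotations: Dict[str, RotationMatrix] | None,
) -> np.ndarray:
    A = (rotations or {}).get(cfg.linked_sensor)
    g = actuator_vector(cfg.C, e)
    w = to_actuator_frame(A, g) if A is not None else g
    return project_to_plane(cfg.G, w)


# ---------------------------------------------------------------------------
# teaching algorithms


def alg_c_alpha(
    state: TeachState,
    e: ErrorVector,
    velocity: np.ndarray,
    position: np.ndarray,
    configs: Sequence[ActuatorConfig],
    t: float,
    rotations: Dict[str, RotationMatrix] | None = None,
    period_ended: bool = False,
) -> List[ActuatorCommand]:
    """Discrete Cα regulator tick; emits at most one command per period.

    Every tick updates the per-period peak |oᵢ|; at the period boundary
    the peak actuator is gated by the ``len``/``elaps`` thresholds and by
    the outward-crossing test against the trajectory centroid.
    """
    for cfg in configs:
        o = _compute_o(cfg, e, rotations)
        norm = float(np.linalg.norm(o))
        peak = state.period_peak.get(cfg.actuator_id)
        if peak is None or norm > peak[0]:
            state.period_peak[cfg.actuator_id] = (norm, o.copy())

    if not period_ended or not state.period_peak:
        return []

    act_id, (norm, o_act) = max(
        state.period_peak.items(), key=lambda kv: kv[1][0]
    )
    state.period_peak = {}

    if norm <= state.len_threshold:
        return []
    if t - state.last_activation.get(act_id, -np.inf) <= state.elaps:
        return []
    if state.centroid is not None:
        radial = np.asarray(position, float) - state.centroid
        r = np.linalg.norm(radial)
        if r == 0.0:
            return []
        u = radial / r
        outward = float(e.components @ u) > 0.0 and float(
            np.asarray(velocity, float) @ u
        ) > 0.0
        if not outward:
            return []

    cfg = next(c for c in configs if c.actuator_id == act_id)
    unit = select_unit(o_act, cfg.unit_directions)
    state.last_activation[act_id] = t
    return [ActuatorCommand(actuator_id=act_id, unit_id=unit, t=t)]


def _crossed(tau_prev: float, tau: float, trigger: float, w: int) -> bool:
    """Did τ pass the trigger probe moving forward on the period circle?"""
    delta = (tau - tau_prev) % w
    if delta == 0.0 or delta > w / 2:  # no advance, or an apparent jump back
        return False
    offset = (trigger - tau_prev) % w
    return 0.0 < offset <= delta


def alg_c_beta(
    state: TeachState,
    trigger: BetaTrigger,
    tpe: TimePointEstimate,
    t: float,
) -> List[ActuatorCommand]:
    """Time-triggered Cβ cue: fire when τ crosses the configured probe."""
    cmds: List[ActuatorCommand] = []
    if tpe.reliable and state.beta_last_tau is not None:
        if _crossed(state.beta_last_tau, tpe.tau, float(trigger.trigger_probe), tpe.w):
            key = f"beta:{trigger.actuator_id}"
            if t - state.last_activation.get(key, -np.inf) > trigger.min_spacing:
                state.last_activation[key] = t
                cmds.append(
                    ActuatorCommand(
                        actuator_id=trigger.actuator_id,
                        unit_id=trigger.unit_id,
                        t=t,
                    )
                )
    if tpe.reliable:
        state.beta_last_tau = tpe.tau
    return cmds


# ---------------------------------------------------------------------------
# the per-tick dispatcher


@dataclass
class TeachConfig:
    """Static wiring of one teaching session.

    ``time_patterns`` may be a mapping index→pattern or a sequence of
    (index, pattern) pairs — the latter allows several time patterns per
    signal (e.g. one per motion class), with the per-tick aggregation
    keeping whichever matches best.
    """

    actuators: Sequence[ActuatorConfig]
    shape_patterns: Dict[int, Pattern1D]
    time_patterns: Dict[int, Pattern1D] | Sequence[Tuple[int, Pattern1D]]
    beta_trigger: Optional[BetaTrigger] = None
    k: int = 3
    n_best: int = 3
    h_max: float = 0.05
    n_avg: int = 10
    grid: Optional[MatchGrid] = None  # classification grid
    sync_grid: Optional[MatchGrid] = None  # time-point grid (default: SYNC_GRID)
    label_alpha: str = "c_alpha"
    label_beta: str = "c_beta"

    def __post_init__(self) -> None:
        if isinstance(self.time_patterns, dict):
            self.time_patterns = list(self.time_patterns.items())
        else:
            self.time_patterns = list(self.time_patterns)
        if not self.shape_patterns or not self.time_patterns:
            raise ConfigurationError("shape and time patterns are required")
        ws = {p.w for _, p in self.time_patterns}
        if len(ws) != 1:
            raise ConfigurationError(f"time patterns must share their period, got {ws}")

    def trajectory_centroid(self) -> np.ndarray:
        """Centre of the taught closed trajectory in shape-signal space."""
        return np.array(
            [self.shape_patterns[i].probes.mean() for i in sorted(self.shape_patterns)]
        )


def teach_step(
    bank: PatternBank,
    S_cur: MultiSignal,
    state: TeachState,
    config: TeachConfig,
    t: float,
    rotations: Dict[str, RotationMatrix] | None = None,
) -> Tuple[ClassDecision | str, List[ActuatorCommand]]:
    """One 10 ms tick of the teaching loop.

    Synchronizes against the time patterns, re-classifies once per
    detected period (switching algorithms only after two consecutive
    agreeing decisions), and runs the current class's algorithm.  Returns
    the latest class decision (or ``"hold"`` before/without sync) and any
    emitted commands.
    """
    if bank.n_pairs < 1:
        raise ConfigurationError("empty pattern bank")
    if state.centroid is None:
        state.centroid = config.trajectory_centroid()

    candidates = [
        time_point_1d(pat, S_cur[i], grid=config.sync_grid)
        for i, pat in config.time_patterns
        if i in S_cur.signals
    ]
    if not candidates:
        raise ConfigurationError("no time-pattern signal present in S_cur")
    w = config.time_patterns[0][1].w
    tpe = aggregate_time_point(
        candidates, w=w, n_best=config.n_best, h_max=config.h_max
    )

    period_ended = False
    if tpe.reliable:
        if state.last_tau is not None:
            period_ended = (tpe.tau - state.last_tau) < -w / 2
        state.last_tau = tpe.tau

    if period_ended:
        decision = classify_knn(bank, S_cur, k=config.k, grid=config.grid)
        state.last_decision = decision
        if decision.label == state.pending_label:
            state.pending_count += 1
        else:
            state.pending_label, state.pending_count = decision.label, 1
        if state.pending_count >= 2 or state.current_label is None:
            state.current_label = decision.label

    if not tpe.reliable:
        return "hold", []

    decision_out: ClassDecision | str = state.last_decision or "hold"
    if state.current_label is None:
        return decision_out, []

    e = motion_error(config.shape_patterns, S_cur, tpe, n_avg=config.n_avg)
    mapping = e.mapping
    dt = 1.0 / S_cur.sample_rate
    position = np.array([S_cur[i].values[-1] for i in mapping])
    if S_cur.m >= 2:
        velocity = np.array(
            [(S_cur[i].values[-1] - S_cur[i].values[-2]) / dt for i in mapping]
        )
    else:
        velocity = np.zeros(len(mapping))

    cmds: List[ActuatorCommand] = []
    if state.current_label == config.label_alpha:
        cmds = alg_c_alpha(
            state,
            e,
            velocity,
            position,
            config.actuators,
            t,
            rotations=rotations,
            period_ended=period_ended,
        )
    elif state.current_label == config.label_beta and config.beta_trigger:
        cmds = alg_c_beta(state, config.beta_trigger, tpe, t)
    return decision_out, cmds


def run_session(
    S_full: MultiSignal,
    bank: PatternBank,
    config: TeachConfig,
    state: TeachState | None = None,
    stride: int = 1,
) -> Tuple[List[dict], List[ActuatorCommand]]:
    """Drive ``teach_step`` over a whole preprocessed recording.

    Replays the recording tick by tick (every ``stride`` samples) with a
    trailing one-period window, as the online loop would see it; the IIR
    filter and cumulative integration are causal, so the replay matches
    online processing.  Returns the per-tick log and all commands.
    """
    state = state or TeachState()
    w = config.time_patterns[0][1].w
    log: List[dict] = []
    commands: List[ActuatorCommand] = []
    from dataclasses import replace as _replace

    for m in range(w, S_full.m + 1, stride):
        t = (m - 1) / S_full.sample_rate
        S_cur = MultiSignal(
            {
                i: _replace(s, values=s.values[:m][-w:])
                for i, s in S_full.signals.items()
            }
        )
        decision, cmds = teach_step(bank, S_cur, state, config, t)
        commands.extend(cmds)
        log.append(
            {
                "t": t,
                "tau": state.last_tau,
                "reliable": decision != "hold",
                "label": state.current_label or "",
                "actuator_id": cmds[0].actuator_id if cmds else "",
                "unit_id": cmds[0].unit_id if cmds else "",
            }
        )
    return log, commands
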