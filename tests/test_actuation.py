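"""Actuator algebra, unit selection, Cα/Cβ gating, and the dispatcher."""

import numpy as np
import pytest

from motiontutor.actuation import (
    ActuatorConfig,
    BetaTrigger,
    TeachConfig,
    TeachState,
    actuator_vector,
    alg_c_alpha,
    alg_c_beta,
    project_to_plane,
    run_session,
    select_unit,
    to_actuator_frame,
)
from motiontutor.errors import ConfigurationError, InvalidInputError
from motiontutor.signals import quat_to_rotation, select_signals
from motiontutor.synchronization import ErrorVector, TimePointEstimate
from motiontutor.virtual_learner import CLASS_ALPHA, CLASS_BETA, LearnerConfig, simulate


def _rot_z(deg):
    ang = np.deg2rad(deg) / 2
    return quat_to_rotation((0, 0, np.sin(ang), np.cos(ang)))


class TestActuatorAlgebra:
    def test_selector_matrix(self):
        C = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        e = ErrorVector(components=[0.05, -0.02], mapping=(6, 8))
        assert np.allclose(actuator_vector(C, e), [0.05, -0.02, 0.0])

    def test_zero_error_zero_vector(self):
        C = np.ones((3, 2))
        assert np.allclose(actuator_vector(C, np.zeros(2)), 0.0)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        C = rng.normal(size=(3, 4))
        e1, e2 = rng.normal(size=4), rng.normal(size=4)
        assert np.allclose(
            actuator_vector(C, e1 + e2),
            actuator_vector(C, e1) + actuator_vector(C, e2),
            atol=1e-12,
        )

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            actuator_vector(np.ones((3, 2)), np.ones(3))

    def test_actuator_frame_rotation_preserves_norm(self):
        rng = np.random.default_rng(1)
        q = rng.normal(size=4)
        A = quat_to_rotation(q)
        g = rng.normal(size=3)
        w = to_actuator_frame(A, g)
        assert np.linalg.norm(w) == pytest.approx(np.linalg.norm(g), abs=1e-12)

    def test_quarter_turn_hand_product(self):
        w = to_actuator_frame(_rot_z(90), [1.0, 0.0, 0.0])
        assert np.allclose(w, [0, 1, 0], atol=1e-12)

    def test_plane_projection_axis_selector(self):
        G = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        assert np.allclose(project_to_plane(G, [1.0, 2.0, 3.0]), [1.0, 3.0])
        assert np.allclose(project_to_plane(G, [0.0, 5.0, 0.0]), [0.0, 0.0])

    def test_in_plane_rotation_preserves_norm(self):
        ang = np.deg2rad(30)
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        G = R @ np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        w = np.array([0.3, 0.0, -0.4])  # in-plane (x, z)
        assert np.linalg.norm(project_to_plane(G, w)) == pytest.approx(0.5)


class TestUnitSelection:
    @pytest.mark.parametrize(
        "o, expected",
        [((0.05, 0.01), 0), ((0.0, 0.1), 1), ((-0.2, 0.0), 2), ((0.0, -0.3), 3)],
    )
    def test_nearest_sector(self, o, expected):
        assert select_unit(np.array(o)) == expected

    def test_rotating_by_90_advances_unit(self):
        o = np.array([0.05, 0.01])
        R = np.array([[0.0, -1.0], [1.0, 0.0]])
        for n in range(4):
            assert select_unit(np.linalg.matrix_power(R, n) @ o) == n

    def test_zero_vector_rejected(self):
        with pytest.raises(InvalidInputError):
            select_unit(np.zeros(2))


def _alpha_fixture():
    C = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])
    G = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    cfg = ActuatorConfig(actuator_id="wrist", C=C, G=G)
    state = TeachState()
    state.centroid = np.zeros(2)
    return cfg, state


class TestAlgCAlpha:
    def _run_period(self, state, cfg, e_mag, t, velocity=(1.0, 0.0), position=(1.0, 0.0)):
        e = ErrorVector(components=[e_mag, 0.0], mapping=(6, 8))
        return alg_c_alpha(
            state, e, np.array(velocity), np.array(position), [cfg], t, period_ended=True
        )

    def test_command_when_all_gates_pass(self):
        cfg, state = _alpha_fixture()
        cmds = self._run_period(state, cfg, 0.04, t=3.0)
        assert len(cmds) == 1 and cmds[0].actuator_id == "wrist"

    def test_below_len_threshold_suppressed(self):
        cfg, state = _alpha_fixture()
        assert self._run_period(state, cfg, 0.02, t=3.0) == []

    def test_elaps_spacing_enforced(self):
        cfg, state = _alpha_fixture()
        assert len(self._run_period(state, cfg, 0.05, t=3.0)) == 1
        assert self._run_period(state, cfg, 0.05, t=4.0) == []  # 1 s later
        assert len(self._run_period(state, cfg, 0.05, t=6.0)) == 1  # > 2.5 s

    def test_inward_motion_gated_off(self):
        cfg, state = _alpha_fixture()
        # radial velocity negative: moving back inside the boundary
        cmds = self._run_period(state, cfg, 0.05, t=3.0, velocity=(-1.0, 0.0))
        assert cmds == []

    def test_inside_error_gated_off(self):
        cfg, state = _alpha_fixture()
        # error points inward (negative radial component)
        cmds = self._run_period(state, cfg, -0.05, t=3.0)
        assert cmds == []


class TestAlgCBeta:
    def _tpe(self, tau, reliable=True, w=200):
        return TimePointEstimate(tau=tau, w=w, candidates=[(tau, 0.01)], reliable=reliable)

    def test_exactly_one_command_per_period_sweep(self):
        trig = BetaTrigger(actuator_id="a", unit_id=2, trigger_probe=120, min_spacing=0.5)
        state = TeachState()
        cmds = []
        t = 0.0
        for _ in range(3):  # three full periods
            for tau in range(1, 201, 4):
                cmds += alg_c_beta(state, trig, self._tpe(float(tau)), t)
                t += 0.04
        assert len(cmds) == 3
        assert all(c.unit_id == 2 for c in cmds)

    def test_unreliable_sync_never_fires(self):
        trig = BetaTrigger(actuator_id="a", unit_id=0, trigger_probe=50, min_spacing=0.0)
        state = TeachState()
        t = 0.0
        total = []
        for tau in list(range(1, 201, 4)) * 2:
            total += alg_c_beta(state, trig, self._tpe(float(tau), reliable=False), t)
            t += 0.04
        assert total == []

    def test_trigger_at_wrap_boundary(self):
        trig = BetaTrigger(actuator_id="a", unit_id=1, trigger_probe=1, min_spacing=0.5)
        state = TeachState()
        cmds = []
        t = 0.0
        for _ in range(3):  # the wrap 197 → 1 is crossed twice
            for tau in range(1, 201, 4):
                cmds += alg_c_beta(state, trig, self._tpe(float(tau)), t)
                t += 0.04
        assert len(cmds) == 2


@pytest.fixture(scope="module")
def teach_setup(reference_patterns):
    refs = reference_patterns
    time_pairs = [
        (i, p)
        for mode in (CLASS_ALPHA, CLASS_BETA)
        for i, p in refs[mode].members.items()
        if "time" in p.roles
    ]
    shape = {i: p for i, p in refs[CLASS_ALPHA].members.items() if "shape" in p.roles}
    C = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])
    G = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    actuator = ActuatorConfig(actuator_id="wrist", C=C, G=G)
    trigger = BetaTrigger(actuator_id="wrist", unit_id=0, trigger_probe=120, min_spacing=1.0)
    return TeachConfig(
        actuators=[actuator],
        shape_patterns=shape,
        time_patterns=time_pairs,
        beta_trigger=trigger,
        k=3,
    )


class TestTeachStep:
    def test_alpha_session_runs_only_alpha_algorithm(self, training_bank, teach_setup):
        stream, _ = simulate(LearnerConfig(class_mode=CLASS_ALPHA, duration=12.0, seed=21))
        S = select_signals([stream], (0, 2, 6, 8), period_w=200)
        log, cmds = run_session(S, training_bank, teach_setup)
        labels = {row["label"] for row in log if row["label"]}
        assert labels == {CLASS_ALPHA}
        # spacing respects elaps
        times = [c.t for c in cmds]
        assert all(t2 - t1 > 2.5 for t1, t2 in zip(times, times[1:]))

    def test_beta_session_fires_once_per_period(self, training_bank, teach_setup):
        stream, truth = simulate(LearnerConfig(class_mode=CLASS_BETA, duration=14.0, seed=22))
        S = select_signals([stream], (0, 2, 6, 8), period_w=200)
        log, cmds = run_session(S, training_bank, teach_setup)
        labels = {row["label"] for row in log if row["label"]}
        assert labels == {CLASS_BETA}
        # one command per period after the warm-up period
        times = np.array([c.t for c in cmds])
        assert len(times) >= 4
        assert np.all(np.diff(times) == pytest.approx(2.0, abs=0.3))
        # commands land near the configured trigger probe
        for t in times:
            probe = truth["probe"][int(round(t * 100))]
            assert abs((probe - 120 + 100) % 200 - 100) <= 6

    def test_empty_bank_rejected(self):
        from motiontutor.patterns import PatternBank

        with pytest.raises(ConfigurationError):
            PatternBank(entries=[])
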