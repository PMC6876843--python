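import io
import math

import numpy as np
import pytest
from scipy.stats import chisquare

from arenatrack.closed_loop import (
    CommandLog,
    OptomotorConfig,
    OptomotorController,
    SerialLineSink,
    SpeedContingentController,
    YMazeController,
    fit_registration,
    render_pinwheel,
)
from arenatrack.metrics import ARMS


class TestRegistration:
    def test_identity_correspondences(self, rng):
        pts = rng.uniform(0, 100, size=(9, 2))
        reg = fit_registration(pts, pts)
        assert np.allclose(reg.matrix / reg.matrix[2, 2], np.eye(3), atol=1e-8)

    def test_recovers_known_affine_map(self):
        g = np.array([(x, y) for x in (0, 50, 100) for y in (0, 50, 100)], float)
        A = np.array([[1.2, 0.1, 5.0], [-0.05, 0.9, -3.0], [0.0, 0.0, 1.0]])
        target = (np.column_stack([g, np.ones(9)]) @ A.T)[:, :2]
        reg = fit_registration(g, target)
        assert reg.residuals(g, target).max() < 1e-6

    def test_recovers_projective_map(self):
        g = np.array([(x, y) for x in (0, 40, 80) for y in (0, 40, 80)], float)
        H = np.array([[1.1, 0.05, 2.0], [0.02, 0.95, -1.0], [1e-4, -2e-4, 1.0]])
        homo = np.column_stack([g, np.ones(9)]) @ H.T
        target = homo[:, :2] / homo[:, 2:3]
        reg = fit_registration(g, target)
        assert reg.residuals(g, target).max() < 1e-6

    def test_noisy_points_fit_within_pixel(self, rng):
        g = np.array([(x, y) for x in range(0, 120, 30) for y in range(0, 120, 30)],
                     float)
        target = g * 1.5 + 20 + rng.normal(0, 0.5, size=g.shape)
        reg = fit_registration(g, target)
        rmse = float(np.sqrt((reg.residuals(g, target) ** 2).mean()))
        assert rmse < 1.0

    def test_too_few_points_raises(self):
        p = np.array([[0, 0], [1, 0], [0, 1]], float)
        with pytest.raises(ValueError):
            fit_registration(p, p)

    def test_collinear_points_raise(self):
        p = np.column_stack([np.arange(6.0), np.arange(6.0)])
        with pytest.raises(ValueError):
            fit_registration(p, p * 2)


class TestYMazeController:
    def _random_session(self, seed, n_rois=4, n_events=300):
        rng = np.random.default_rng(seed)
        ctrl = YMazeController(n_rois, seed=seed)
        occupied = [None] * n_rois
        frame = 0
        for _ in range(n_events):
            labels = []
            for rid in range(n_rois):
                if occupied[rid] is None or rng.uniform() < 0.4:
                    nxt = rng.choice([a for a in ARMS if a != occupied[rid]])
                    occupied[rid] = str(nxt)
                    labels.append("center")  # pass through the center first
                else:
                    labels.append(occupied[rid])
            ctrl.step(frame, labels)
            frame += 1
            ctrl.step(frame, list(occupied))
            frame += 1
        return ctrl

    def test_lit_arm_never_occupied(self):
        ctrl = self._random_session(seed=11)
        assert len(ctrl.trials) > 50
        for rec in ctrl.trials:
            assert rec.stimulus["lit_arm"] != rec.outcome["from_arm"]
        # the currently lit arm never matches the arm the animal entered
        # at the moment of lighting (it is lit among the unoccupied two)
        for rid in range(ctrl.n_rois):
            if ctrl.lit_arm[rid] is not None:
                assert ctrl.lit_arm[rid] != ctrl.last_arm[rid]

    def test_animal_staying_put_emits_nothing(self):
        ctrl = YMazeController(1, seed=0)
        ctrl.step(0, ["arm_A"])  # initial trial setup
        n0 = len(ctrl.log)
        for f in range(1, 200):
            ctrl.step(f, ["arm_A"])
        assert len(ctrl.log) == n0

    def test_missing_position_freezes_state(self):
        ctrl = YMazeController(1, seed=0)
        ctrl.step(0, ["arm_A"])
        lit = ctrl.lit_arm[0]
        ctrl.step(1, [None])
        assert ctrl.lit_arm[0] == lit and len(ctrl.trials) == 0

    def test_unlit_arm_choice_is_uniform(self):
        """Across many trials the new LED splits evenly over the two
        unoccupied arms (chi-square test)."""
        ctrl = self._random_session(seed=5, n_rois=8, n_events=2000)
        # classify each trial's lit arm relative to the origin arm
        picks = {"ccw": 0, "cw": 0}
        for rec in ctrl.trials:
            lit = rec.stimulus["lit_arm"]
            frm = rec.outcome["from_arm"]
            ccw = ARMS[(ARMS.index(frm) + 1) % 3]
            picks["ccw" if lit == ccw else "cw"] += 1
        stat, p = chisquare(list(picks.values()))
        assert p > 0.001

    def test_command_log_reproducible(self):
        a = self._random_session(seed=3).log.to_bytes()
        b = self._random_session(seed=3).log.to_bytes()
        assert a == b


class TestOptomotorController:
    def _ctrl(self, **kw):
        cfg = OptomotorConfig(speed_threshold=2.0, **kw)
        return OptomotorController(
            arenas=[((60.0, 60.0), 50.0)], cfg=cfg, seed=1
        )

    def test_stationary_animal_never_stimulated(self):
        ctrl = self._ctrl()
        for f in range(1000):
            ctrl.step(f, [(60.0, 60.0)], [0.0])
        assert len(ctrl.trials) == 0

    def test_trial_duration_in_frames(self):
        ctrl = self._ctrl()
        done = []
        for f in range(400):
            done += ctrl.step(f, [(60.0, 60.0)], [5.0])
        assert done, "no trial completed"
        rec = done[0]
        assert rec.offset - rec.onset == int(2.0 * 60.0)

    def test_edge_gate_blocks_trials(self):
        ctrl = self._ctrl()
        # within 0.25 * radius of the wall
        for f in range(500):
            ctrl.step(f, [(60.0 + 45.0, 60.0)], [5.0])
        assert len(ctrl.trials) == 0

    def test_iti_respected_over_long_session(self):
        ctrl = self._ctrl()
        for f in range(20000):
            ctrl.step(f, [(60.0, 60.0)], [5.0])
        onsets = [t.onset for t in ctrl.trials]
        offsets = [t.offset for t in ctrl.trials]
        assert len(onsets) > 10
        for prev_off, nxt_on in zip(offsets, onsets[1:]):
            assert nxt_on - prev_off >= int(2.0 * 60.0)

    def test_pinwheel_center_follows_registration(self):
        from arenatrack.closed_loop import RegistrationMap

        reg = RegistrationMap(np.array([[2.0, 0, 10], [0, 2.0, -5], [0, 0, 1]]))
        cfg = OptomotorConfig(speed_threshold=2.0)
        ctrl = OptomotorController([((60.0, 60.0), 50.0)], cfg=cfg,
                                   registration=reg, seed=0)
        ctrl.step(0, [(60.0, 60.0)], [5.0])
        cmd = ctrl.log.commands[-1]
        assert cmd.payload["center"] == [2 * 60.0 + 10, 2 * 60.0 - 5]


class TestSpeedContingent:
    def test_baseline_is_always_off(self):
        ctrl = SpeedContingentController(1, fps=10.0)
        for f in range(100):
            ctrl.step(f, [50.0])
        assert all(c.kind != "light_on" for c in ctrl.log)

    def test_lit_when_slow_rule_with_threshold(self):
        ctrl = SpeedContingentController(
            1, schedule=[("lit_when_slow", 100)], threshold=6.8
        )
        ctrl.step(0, [10.0])
        assert not ctrl.lit[0]  # fast -> off
        ctrl.step(1, [3.0])
        assert ctrl.lit[0]
        ctrl.step(2, [6.8])
        assert ctrl.lit[0]  # at threshold counts as slow

    def test_missing_speed_fails_safe(self):
        ctrl = SpeedContingentController(1, schedule=[("lit_when_slow", 10)])
        ctrl.step(0, [1.0])
        assert ctrl.lit[0]
        ctrl.step(1, [None])
        assert not ctrl.lit[0]

    def test_square_wave_commands_alternate(self):
        fps = 10
        ctrl = SpeedContingentController(
            1, schedule=[("lit_when_fast", 1000)], threshold=5.0
        )
        for f in range(100):
            speed = 10.0 if (f // fps) % 2 == 0 else 1.0
            ctrl.step(f, [speed])
        kinds = [c.kind for c in ctrl.log]
        assert kinds == ["light_on", "light_off"] * 5

    def test_default_schedule_is_eight_by_eight_minutes(self):
        ctrl = SpeedContingentController(1, fps=30.0)
        assert len(ctrl.schedule) == 8
        assert all(n == 8 * 60 * 30 for _, n in ctrl.schedule)
        assert ctrl.threshold == 6.8


class TestPinwheel:
    def test_zero_contrast_is_uniform(self):
        patch = render_pinwheel((40, 40), (20, 20), 0.0, 0.0, 6)
        assert np.all(patch == 0.5)

    def test_full_period_phase_is_identical(self):
        a = render_pinwheel((40, 40), (20, 20), 0.3, 1.0, 6)
        b = render_pinwheel((40, 40), (20, 20), 0.3 + 2 * math.pi, 1.0, 6)
        assert np.array_equal(a, b)

    def test_phase_step_arithmetic(self):
        # 360 deg/s at 60 Hz refresh advances 6 degrees per frame
        assert math.degrees(math.radians(360.0) / 60.0) == pytest.approx(6.0)

    def test_contrast_out_of_range_raises(self):
        with pytest.raises(ValueError):
            render_pinwheel((10, 10), (5, 5), 0.0, 1.5, 6)


class TestSerialSink:
    def test_three_byte_packets(self):
        buf = io.BytesIO()
        log = CommandLog(sink=SerialLineSink(buf))
        from arenatrack.closed_loop import StimulusCommand

        log.emit(StimulusCommand(0, 3, "led_on", {"arm": "arm_B"}))
        log.emit(StimulusCommand(1, 3, "led_off", {"arm": "arm_B"}))
        assert buf.getvalue() == bytes([3, 1, 1, 3, 2, 1])
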