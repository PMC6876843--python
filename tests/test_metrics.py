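import math

import numpy as np
import pytest

from arenatrack import metrics as met
from arenatrack.roi import ROI, ROISet, add_ymaze_subregions
from arenatrack.synth import WalkerModel, scripted_ymaze_positions, simulate_walkers


def mixture_logpdf_minimum(w1, mu1, s1, mu2, s2):
    """Oracle: dense-grid minimum of a two-Gaussian mixture density."""
    grid = np.linspace(min(mu1, mu2) - 1, max(mu1, mu2) + 1, 20001)

    def pdf(x, mu, s):
        return np.exp(-0.5 * ((x - mu) / s) ** 2) / (s * math.sqrt(2 * math.pi))

    dens = w1 * pdf(grid, mu1, s1) + (1 - w1) * pdf(grid, mu2, s2)
    lo = grid.searchsorted(mu1)
    hi = grid.searchsorted(mu2)
    return grid[lo + np.argmin(dens[lo:hi])]


@pytest.fixture
def ymaze_roi():
    roi = ROI(0, "circle", (60.0, 60.0), 50.0)
    rois = ROISet([roi], (120, 120))
    add_ymaze_subregions(roi, rois.image_size, center_radius=12.0)
    return roi, rois


class TestSpeed:
    def test_stationary_is_zero(self):
        sp = met.speed(np.tile([3.0, 4.0], (10, 1)), fps=8.0)
        assert np.all(sp.values[1:] == 0.0)

    def test_pixel_scale_conversion(self):
        pos = np.column_stack([np.arange(0, 20, 2.0), np.zeros(10)])
        sp = met.speed(pos, fps=8.0, px2mm=0.25)
        assert sp.units == "mm/s"
        assert np.allclose(sp.values[1:], 4.0)

    def test_gap_propagates_to_both_intervals(self):
        pos = np.array([[0, 0], [1, 0], [np.nan, np.nan], [3, 0], [4, 0]])
        sp = met.speed(pos, fps=1.0)
        assert np.isnan(sp.values[2]) and np.isnan(sp.values[3])
        assert np.isfinite(sp.values[4])


class TestMovementThreshold:
    @pytest.mark.parametrize("w1", [0.5, 0.9])
    def test_recovers_mixture_density_minimum(self, rng, w1):
        n = 40000
        comp = rng.uniform(size=n) < w1
        logv = np.where(
            comp, rng.normal(-2.0, 0.5, n), rng.normal(1.0, 0.5, n)
        )
        sp = met.SpeedSeries(np.exp(logv), fps=30.0)
        thr = met.movement_threshold(sp)
        want = mixture_logpdf_minimum(w1, -2.0, 0.5, 1.0, 0.5)
        assert abs(math.log(thr) - want) < 0.15

    def test_unimodal_raises(self, rng):
        sp = met.SpeedSeries(np.exp(rng.normal(0.0, 0.5, 5000)), fps=30.0)
        with pytest.raises(ValueError, match="unimodal"):
            met.movement_threshold(sp)

    def test_too_few_samples_raises(self, rng):
        sp = met.SpeedSeries(np.exp(rng.normal(0, 1, 100)), fps=30.0)
        with pytest.raises(ValueError):
            met.movement_threshold(sp)


class TestBouts:
    def test_run_length_example(self):
        sp = met.SpeedSeries(np.array([0.0, 5, 5, 0, 5]), fps=1.0)
        bs = met.bouts(sp, threshold=1.0)
        assert [(s, e) for s, e, _ in bs.bouts] == [(1, 2), (4, 4)]

    def test_all_below_threshold_empty(self):
        sp = met.SpeedSeries(np.full(10, 0.1), fps=1.0)
        assert len(met.bouts(sp, 1.0)) == 0

    def test_missing_breaks_a_run(self):
        v = np.array([5.0, 5, np.nan, 5, 5])
        bs = met.bouts(met.SpeedSeries(v, fps=1.0), 1.0)
        assert [(s, e) for s, e, _ in bs.bouts] == [(0, 1), (3, 4)]

    def test_bout_durations_match_generator_dwell(self, rng):
        """Mean move-bout length recovers the generator's dwell parameter."""
        fps = 30.0
        model = WalkerModel(mean_move_s=5.0, mean_pause_s=5.0)
        _, moving = simulate_walkers(
            model, n=12, duration_s=400.0, fps=fps, rng=rng, arena_radius=50.0
        )
        durations = []
        for row in moving:
            d = np.diff(np.concatenate([[0], row.astype(int), [0]]))
            starts = np.nonzero(d == 1)[0]
            ends = np.nonzero(d == -1)[0]
            durations.extend((ends - starts) / fps)
        mean_dwell = float(np.mean(durations))
        assert abs(mean_dwell - 5.0) / 5.0 < 0.1


class TestYmazeScoring:
    def test_single_choice_toward_lit(self, ymaze_roi):
        roi, rois = ymaze_roi
        pos = scripted_ymaze_positions(roi, ["arm_A", "arm_B"])
        lit = ["arm_B"] * len(pos)
        seq = met.score_ymaze(pos, roi, rois, lit)
        assert len(seq) == 1
        c = seq.choices[0]
        assert (c.from_arm, c.to_arm, c.photo_choice) == ("arm_A", "arm_B", "toward_lit")

    def test_reentry_is_not_a_choice(self, ymaze_roi):
        roi, rois = ymaze_roi
        pos = scripted_ymaze_positions(roi, ["arm_A", "arm_A"])
        seq = met.score_ymaze(pos, roi, rois, [None] * len(pos))
        assert len(seq) == 0

    def test_scripted_sequence_matches_script(self, ymaze_roi, rng):
        roi, rois = ymaze_roi
        arms = ["arm_A"]
        for _ in range(20):
            arms.append(
                rng.choice([a for a in met.ARMS if a != arms[-1]])
            )
        pos = scripted_ymaze_positions(roi, arms)
        lit = ["arm_A"] * len(pos)  # constant lit arm; entries from it drop photo
        seq = met.score_ymaze(pos, roi, rois, lit)
        assert len(seq) == 20
        assert [c.from_arm for c in seq] == arms[:-1]
        assert [c.to_arm for c in seq] == arms[1:]

    def test_turn_direction_convention(self):
        # counterclockwise neighbor (on screen) is a left turn
        assert met.turn_direction("arm_A", "arm_B") == "L"
        assert met.turn_direction("arm_B", "arm_C") == "L"
        assert met.turn_direction("arm_A", "arm_C") == "R"


class TestBiases:
    def test_counting_example(self, ymaze_roi):
        seq = met.ChoiceSequence(
            [
                met.Choice(0, "arm_A", "arm_C", "arm_C", "R", "toward_lit"),
                met.Choice(1, "arm_C", "arm_A", "arm_B", "L", "away"),
                met.Choice(2, "arm_A", "arm_C", "arm_C", "R", "toward_lit"),
                met.Choice(3, "arm_C", "arm_B", "arm_B", "R", "toward_lit"),
            ]
        )
        out = met.biases(seq)
        assert out["turn_bias"] == 0.75
        assert out["photo_bias"] == 0.75

    def test_all_left_turns(self):
        seq = met.ChoiceSequence(
            [met.Choice(i, "arm_A", "arm_B", None, "L", None) for i in range(5)]
        )
        assert met.biases(seq)["turn_bias"] == 0.0

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            met.biases(met.ChoiceSequence([]))

    def test_random_choices_near_half(self, rng):
        n = 830
        seq = met.ChoiceSequence([])
        for i in range(n):
            from_arm = rng.choice(met.ARMS)
            others = [a for a in met.ARMS if a != from_arm]
            to = rng.choice(others)
            lit = rng.choice(others)
            seq.choices.append(
                met.Choice(
                    i, from_arm, to, lit,
                    met.turn_direction(from_arm, to),
                    "toward_lit" if to == lit else "away",
                )
            )
        out = met.biases(seq)
        tol = 3 * math.sqrt(0.25 / n)
        assert abs(out["turn_bias"] - 0.5) < tol
        assert abs(out["photo_bias"] - 0.5) < tol


class TestOptomotorIndex:
    def test_pure_with_rotation_is_plus_one(self):
        h = np.linspace(0, 4 * math.pi, 200)
        idx, mean = met.optomotor_index(h, [(0, 199, +1)])
        assert idx[0] == 1.0 and mean == 1.0

    def test_pure_against_rotation_is_minus_one(self):
        h = np.linspace(0, 4 * math.pi, 200)
        idx, _ = met.optomotor_index(h, [(0, 199, -1)])
        assert idx[0] == -1.0

    def test_balanced_rotation_is_zero(self):
        h = np.concatenate([np.linspace(0, math.pi, 50),
                            np.linspace(math.pi, 0, 50)])
        idx, _ = met.optomotor_index(h, [(0, 99, +1)])
        assert abs(idx[0]) < 1e-12

    def test_constant_heading_scores_missing(self):
        h = np.zeros(100)
        idx, mean = met.optomotor_index(h, [(0, 99, +1)])
        assert np.isnan(idx[0])


class TestOccupancyEntries:
    def test_never_enters_lit_arm(self, ymaze_roi):
        roi, rois = ymaze_roi
        pos = scripted_ymaze_positions(roi, ["arm_A", "arm_B", "arm_A"])
        lit = ["arm_C"] * len(pos)
        occ, ent = met.occupancy_entries(pos, roi, rois, lit)
        assert occ == 0.0 and ent == 0.0

    def test_uniform_script_near_third(self, ymaze_roi, rng):
        roi, rois = ymaze_roi
        arms = ["arm_A"]
        for _ in range(150):
            arms.append(rng.choice([a for a in met.ARMS if a != arms[-1]]))
        pos = scripted_ymaze_positions(roi, arms)
        lit = ["arm_B"] * len(pos)
        occ, ent = met.occupancy_entries(pos, roi, rois, lit)
        assert abs(occ - 1 / 3) < 0.12
        assert abs(ent - 1 / 3) < 0.12


class TestHeterogeneityProperty:
    def test_individual_bias_widens_index_distribution(self, rng):
        """Heterogeneous per-individual turning gains produce a wider
        spread of mean optomotor indices than a common-statistics null."""

        def indices(gains):
            means = []
            for g in gains:
                h = np.cumsum(rng.normal(g * 0.1, 0.2, size=600))
                trials = [(k * 60, k * 60 + 59, +1) for k in range(10)]
                means.append(met.optomotor_index(h, trials)[1])
            return np.asarray(means)

        hetero = indices(rng.uniform(-1.0, 1.0, size=40))
        null = indices(np.full(40, 0.3))
        assert np.std(hetero) > np.std(null)
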