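import numpy as np
import pytest

from coprqa.rqa import (
    RqaConfig,
    cycle_delay,
    determinism,
    embed,
    radial_component,
    recurrence_matrix,
    recurrence_rate,
    rqa_from_series,
    rqa_ratio,
    run_rqa,
)
from coprqa.types import CopTrajectory, CycleSet

from rqa_oracle import brute_det, brute_diameter, brute_matrix, brute_rec


class TestComponents:
    def test_circle_radial_is_constant(self, circle_segment):
        r = radial_component(circle_segment(radius=3.0, center=(5.0, 5.0)))
        assert np.allclose(r, 3.0, atol=1e-2)

    def test_pure_ap_oscillation(self):
        ap = np.sin(np.linspace(0, 20, 500))
        seg = CopTrajectory(ml=np.full(500, 2.0), ap=ap, rate_hz=100.0)
        assert np.allclose(radial_component(seg), np.abs(ap - ap.mean()))

    def test_cross_pattern_all_ones(self):
        seg = CopTrajectory(ml=np.array([1.0, -1.0, 0.0, 0.0]),
                            ap=np.array([0.0, 0.0, 1.0, -1.0]), rate_hz=10.0)
        assert np.allclose(radial_component(seg), 1.0)


class TestCycleDelay:
    @pytest.mark.parametrize(
        "lengths,expected",
        [((500, 500, 500), 500), ((400, 500, 600), 500), ((3,), 3)],
    )
    def test_mean_interval_length(self, lengths, expected):
        intervals, pos = [], 0
        for ln in lengths:
            intervals.append((pos, pos + ln))
            pos += ln + 10
        assert cycle_delay(CycleSet(intervals=intervals, rate_hz=100.0)) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cycle_delay(CycleSet(intervals=[], rate_hz=100.0))


class TestEmbed:
    def test_m1_is_identity(self):
        s = np.arange(7.0)
        assert np.array_equal(embed(s, 1, 3)[:, 0], s)

    def test_definition_example(self):
        s = np.array([1.0, 2.0, 3.0, 4.0, 5.0])  # (a..e), m=2, tau=2
        expected = np.array([[1, 3], [2, 4], [3, 5]], float)
        assert np.array_equal(embed(s, 2, 2), expected)

    def test_state_count(self):
        assert embed(np.arange(10.0), 3, 4).shape == (2, 3)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            embed(np.arange(4.0), 3, 2)


class TestRecurrenceMatrix:
    def test_identical_states_all_ones(self):
        r = recurrence_matrix(np.zeros((3, 2)), epsilon=0.5,
                              epsilon_is_fraction=False)
        assert r.all()

    def test_two_far_states_identity(self):
        r = recurrence_matrix(np.array([[0.0], [5.0]]), epsilon=1.0,
                              epsilon_is_fraction=False)
        assert np.array_equal(r, np.eye(2, dtype=bool))

    def test_identical_states_fractional_epsilon_rejected(self):
        with pytest.raises(ValueError, match="absolute epsilon"):
            recurrence_matrix(np.zeros((3, 2)), epsilon=0.1)

    @pytest.mark.parametrize("norm", ["euclidean", "maximum"])
    def test_matches_brute_force(self, norm):
        rng = np.random.default_rng(17)
        states = rng.normal(size=(50, 3))
        eps = 0.3 * brute_diameter([list(s) for s in states], norm)
        r = recurrence_matrix(states, eps, epsilon_is_fraction=False, norm=norm)
        assert np.array_equal(r, brute_matrix([list(s) for s in states], eps, norm))


class TestRecDet:
    def test_all_ones_rec_is_one(self):
        r = np.ones((6, 6), bool)
        assert recurrence_rate(r, theiler=0) == 1.0
        # every diagonal is one maximal run; only the two length-1 corner
        # diagonals fail l_min=2, so DET = 28/30 here and -> 1 as n grows
        assert determinism(r, l_min=2, theiler=0) == pytest.approx(28 / 30)
        big = np.ones((200, 200), bool)
        assert determinism(big, l_min=2, theiler=0) > 0.999

    def test_identity_matrix_rec_zero(self):
        assert recurrence_rate(np.eye(8, dtype=bool), theiler=0) == 0.0

    def test_theiler_excluding_everything_rejected(self):
        with pytest.raises(ValueError, match="Theiler"):
            recurrence_rate(np.ones((4, 4), bool), theiler=4)

    def test_isolated_points_zero_det(self):
        r = np.eye(10, dtype=bool)
        r[0, 5] = r[5, 0] = True
        r[2, 8] = r[8, 2] = True
        assert determinism(r, l_min=2, theiler=0) == 0.0

    def test_no_recurrences_det_missing(self):
        assert np.isnan(determinism(np.eye(5, dtype=bool), l_min=2, theiler=0))

    def test_sinusoid_counts_match_brute_force(self):
        t = np.arange(100)
        s = np.sin(2 * np.pi * t / 25.0)
        states = embed(s, 2, 6)  # tau ~ quarter period
        lstates = [list(v) for v in states]
        eps = 0.10 * brute_diameter(lstates)
        r = recurrence_matrix(states, eps, epsilon_is_fraction=False)
        assert recurrence_rate(r, 0) == pytest.approx(brute_rec(r, 0), abs=0)
        assert determinism(r, 2, 0) == pytest.approx(brute_det(r, 2, 0), abs=0)
        assert np.array_equal(r, brute_matrix(lstates, eps))


class TestRatioAndInvariances:
    def test_ratio_values(self):
        assert rqa_ratio(0.5, 0.9) == pytest.approx(1.8)
        assert rqa_ratio(0.31, 0.31) == 1.0
        assert rqa_ratio(0.31, 1.0) == pytest.approx(3.2258, abs=1e-4)
        assert np.isnan(rqa_ratio(0.0, 0.5))

    def test_periodic_series_high_det(self):
        # cycle-scale delay (as the pipeline uses) on a noiseless oscillation:
        # recurrences organise into long diagonals
        t = np.arange(400)
        s = np.sin(2 * np.pi * t / 48.0)
        for tau in (12, 50):  # quarter-period and near-period delays
            rec, det, ratio, _ = rqa_from_series(
                s, RqaConfig(m=2, tau=tau, epsilon=0.05))
            assert det >= 0.99
            assert ratio == pytest.approx(det / rec, rel=1e-12)

    def test_rec_monotone_in_epsilon(self):
        rng = np.random.default_rng(2)
        s = np.cumsum(rng.normal(size=300))
        prev = -1.0
        for frac in (0.02, 0.05, 0.1, 0.2, 0.5, 1.0):
            rec, *_ = rqa_from_series(s, RqaConfig(m=2, tau=5, epsilon=frac))
            assert rec >= prev
            prev = rec
        assert prev == 1.0  # at the full diameter everything recurs

    def test_offset_and_scale_invariance_with_fractional_epsilon(self):
        rng = np.random.default_rng(8)
        s = rng.normal(size=250)
        cfg = RqaConfig(m=2, tau=3, epsilon=0.15)
        base = rqa_from_series(s, cfg)
        shifted = rqa_from_series(s + 42.0, cfg)
        scaled = rqa_from_series(3.5 * s, cfg)
        assert base[:3] == shifted[:3] == scaled[:3]


class TestRunRqa:
    def test_periodic_beats_noise_and_is_deterministic(self, free_trial_cop,
                                                       free_trial_cycles):
        cfg = RqaConfig(downsample=4)
        res1 = run_rqa(free_trial_cop, free_trial_cycles, cfg)
        res2 = run_rqa(free_trial_cop, free_trial_cycles, cfg)
        assert [(r.rec, r.det, r.ratio) for r in res1] == \
            [(r.rec, r.det, r.ratio) for r in res2]
        assert {r.component for r in res1} == {"radial", "AP", "ML"}

        # white-noise trial with the same cycle structure scores lower DET
        rng = np.random.default_rng(0)
        noise = CopTrajectory(
            ml=rng.normal(size=len(free_trial_cop)),
            ap=rng.normal(size=len(free_trial_cop)),
            rate_hz=free_trial_cop.rate_hz, meta=free_trial_cop.meta,
        )
        res_noise = run_rqa(noise, free_trial_cycles, cfg)
        for quasi, white in zip(res1, res_noise):
            assert quasi.det > white.det
            assert quasi.ratio > white.ratio

    def test_doubling_epsilon_rec_nondecreasing(self, free_trial_cop,
                                                free_trial_cycles):
        r1 = run_rqa(free_trial_cop, free_trial_cycles,
                     RqaConfig(epsilon=0.1, downsample=4))
        r2 = run_rqa(free_trial_cop, free_trial_cycles,
                     RqaConfig(epsilon=0.2, downsample=4))
        for a, b in zip(r1, r2):
            assert b.rec >= a.rec

    def test_too_short_series_rejected(self, free_trial_cop):
        cycles = CycleSet(intervals=[(0, 10)], rate_hz=free_trial_cop.rate_hz)
        with pytest.raises(ValueError, match="shorter than"):
            run_rqa(free_trial_cop, cycles, RqaConfig())
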