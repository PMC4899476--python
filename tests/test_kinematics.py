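"""Kinematics: minimum-jerk profiles, DTW distances, judgment simulation/fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vitalmvpa import (
    dtw_distance,
    duration_grouping_check,
    fit_log_judgment,
    generate_stimulus_set,
    generate_velocity_profile,
    pairwise_dtw_matrix,
    simulate_judgments,
)
from vitalmvpa.kinematics import (
    DTWDistanceMatrix,
    EXEC_TIMES_MS,
    FMRI_PATH_LENGTH_M,
    DEFAULT_JUDGMENT_PARAMS,
)


def brute_force_dtw(a, b):
    """Independent oracle: exhaustive recursion over all monotone warp paths."""
    a, b = list(a), list(b)

    def rec(i, j):
        c = abs(a[i] - b[j])
        if i == 0 and j == 0:
            return c
        best = np.inf
        if i > 0:
            best = min(best, rec(i - 1, j))
        if j > 0:
            best = min(best, rec(i, j - 1))
        if i > 0 and j > 0:
            best = min(best, rec(i - 1, j - 1))
        return c + best

    return rec(len(a) - 1, len(b) - 1)


class TestVelocityProfiles:
    @pytest.mark.parametrize("t_ms,length", sorted(FMRI_PATH_LENGTH_M.items()))
    def test_mean_speed_matches_stimulus_velocities(self, t_ms, length):
        # path length / duration reproduces the three stimulus mean velocities
        traj = generate_velocity_profile(t_ms, length, seed=0)
        assert traj.speed.mean() * t_ms / 1000.0 == pytest.approx(length, rel=1e-9)

    def test_sample_count_and_bell_shape(self):
        traj = generate_velocity_profile(500, 0.3, seed=1)
        assert len(traj.samples) == 50  # 100 Hz x 0.5 s
        speed = traj.speed
        peak = np.argmax(speed)
        assert 0.3 * len(speed) < peak < 0.7 * len(speed)
        assert speed[0] < 0.2 * speed[peak] and speed[-1] < 0.2 * speed[peak]

    def test_vanishing_path_length_gives_vanishing_speed(self):
        traj = generate_velocity_profile(600, 1e-4, seed=0)
        assert np.all(traj.speed < 1e-3)

    @pytest.mark.parametrize("kwargs", [
        {"exec_time_ms": 400, "path_length_m": 0.5},
        {"exec_time_ms": 1000, "path_length_m": -1.0},
        {"exec_time_ms": 0, "path_length_m": 0.5},
    ])
    def test_invalid_arguments_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_velocity_profile(**kwargs)


class TestDTW:
    def test_identical_series_zero(self, rng):
        for _ in range(5):
            a = rng.standard_normal(rng.integers(1, 20))
            assert dtw_distance(a, a) == 0.0

    def test_small_example_matches_enumeration(self):
        assert dtw_distance([0, 1, 2], [0, 2]) == pytest.approx(
            brute_force_dtw([0, 1, 2], [0, 2])
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=6),
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=6),
    )
    def test_matches_exhaustive_path_enumeration(self, a, b):
        assert dtw_distance(a, b) == pytest.approx(brute_force_dtw(a, b), abs=1e-9)

    def test_symmetry_and_nonnegativity(self, rng):
        for _ in range(10):
            a = rng.standard_normal(rng.integers(2, 15))
            b = rng.standard_normal(rng.integers(2, 15))
            d = dtw_distance(a, b)
            assert d >= 0
            assert d == pytest.approx(dtw_distance(b, a))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance([], [1.0])

    def test_normalized_option_divides_by_length_sum(self):
        a, b = [0.0, 1.0, 2.0], [0.0, 2.0]
        assert dtw_distance(a, b, normalize=True) == pytest.approx(
            dtw_distance(a, b) / 5.0
        )


@pytest.fixture(scope="module")
def stimuli():
    return generate_stimulus_set(seed=0)


class TestPairwiseMatrix:
    def test_shape_and_invariants(self, stimuli):
        m = pairwise_dtw_matrix(stimuli, mode="modulus")
        assert m.distances.shape == (36, 36)
        assert np.allclose(m.distances, m.distances.T)
        assert np.allclose(np.diag(m.distances), 0)
        assert np.all(m.distances >= 0)

    def test_entry_matches_direct_dtw(self, stimuli):
        m = pairwise_dtw_matrix(stimuli, mode="vx")
        i, j = 2, 17
        expected = dtw_distance(stimuli[i].channel("vx"), stimuli[j].channel("vx"))
        assert m.distances[i, j] == pytest.approx(expected)

    def test_wrong_count_rejected(self, stimuli):
        with pytest.raises(ValueError):
            pairwise_dtw_matrix(stimuli[:35])

    def test_duration_grouping_recovered(self, stimuli):
        # same-duration actions with different objects are mutually closer
        # than actions executed at different speeds
        rep = duration_grouping_check(pairwise_dtw_matrix(stimuli))
        assert rep.mean_within_level < rep.mean_between_level
        assert rep.grouped_by_duration

    def test_grouping_arithmetic_on_toy_matrix(self):
        labels = (("bottle", 1), ("can", 1), ("bottle", 2), ("can", 2))
        d = np.array(
            [
                [0.0, 1.0, 4.0, 5.0],
                [1.0, 0.0, 6.0, 7.0],
                [4.0, 6.0, 0.0, 2.0],
                [5.0, 7.0, 2.0, 0.0],
            ]
        )
        rep = duration_grouping_check(DTWDistanceMatrix(d, labels))
        assert rep.mean_within_level == pytest.approx((1 + 2) / 2)
        assert rep.mean_between_level == pytest.approx((4 + 5 + 6 + 7) / 4)

    def test_equal_distances_not_grouped(self):
        labels = (("bottle", 1), ("can", 1), ("bottle", 2), ("can", 2))
        d = np.full((4, 4), 3.0)
        np.fill_diagonal(d, 0.0)
        assert not duration_grouping_check(DTWDistanceMatrix(d, labels)).grouped_by_duration


class TestJudgments:
    def test_noiseless_scores_on_log_curve_and_perfect_fit(self):
        j = simulate_judgments(noise_sd=0.0, n_subjects=3, seed=0)
        a, b = DEFAULT_JUDGMENT_PARAMS["vitality"]
        row = j[(j.task == "vitality") & (j.exec_time_ms == 800)].score.unique()
        assert row == pytest.approx(np.clip(a + b * np.log(800), 1, 5))
        icpt, slope, r2 = fit_log_judgment(j, "vitality")
        assert (icpt, slope) == pytest.approx((a, b), rel=1e-6)
        assert r2 == pytest.approx(1.0)

    def test_velocity_scores_shifted_above_vitality(self):
        j = simulate_judgments(noise_sd=0.3, n_subjects=18, seed=4)
        means = j.groupby("task").score.mean()
        assert means["velocity"] > means["vitality"]

    def test_seed_determinism(self):
        a = simulate_judgments(seed=9)
        b = simulate_judgments(seed=9)
        assert a.equals(b)

    def test_slope_recovery_within_monte_carlo_bounds(self):
        # 100 independent cohorts: the fitted slope distribution should
        # center on the generating slope
        slopes = [
            fit_log_judgment(
                simulate_judgments(noise_sd=0.4, n_subjects=18, seed=s), "vitality"
            )[1]
            for s in range(100)
        ]
        gen_slope = DEFAULT_JUDGMENT_PARAMS["vitality"][1]
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - gen_slope) < 2 * se + 1e-3

    def test_pure_noise_has_near_zero_r2(self):
        j = simulate_judgments(
            params={"vitality": (3.0, 0.0)}, noise_sd=5.0, n_subjects=50, seed=2
        )
        _, _, r2 = fit_log_judgment(j, "vitality")
        assert r2 < 0.3

    def test_single_time_point_rejected(self):
        j = simulate_judgments(n_subjects=2, seed=0, exec_times_ms=[1000])
        with pytest.raises(ValueError):
            fit_log_judgment(j, "vitality")
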