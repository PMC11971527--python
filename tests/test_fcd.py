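"""Phase dynamics, FCD construction, and the KS distance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hopffit import (
    DegenerateInputError,
    InvalidInputError,
    PhaseSeries,
    RegionalTimeSeries,
    cosine_similarity,
    fcd,
    instantaneous_phase,
    ks_distance,
    phase_interaction_matrix,
    windowed_mean_interaction,
)

TR = 2.0


def brute_force_ks(s1, s2):
    """Independent ECDF sup-distance by direct enumeration."""
    pts = np.concatenate([s1, s2])
    d = 0.0
    for x in pts:
        f1 = np.mean(np.asarray(s1) <= x)
        f2 = np.mean(np.asarray(s2) <= x)
        d = max(d, abs(f1 - f2))
    return d


class TestInstantaneousPhase:
    def test_cosine_phase_slope_matches_frequency(self):
        t = np.arange(600) * TR
        x = np.cos(2 * np.pi * 0.05 * t)
        ph = instantaneous_phase(RegionalTimeSeries(x[:, None], TR), (0.01, 0.1))
        un = np.unwrap(ph.phases[50:-50, 0])
        slope = np.polyfit(t[50:-50], un, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 0.05, rel=0.02)

    def test_identical_signals_zero_phase_difference(self):
        t = np.arange(400) * TR
        x = np.cos(2 * np.pi * 0.03 * t)
        ph = instantaneous_phase(RegionalTimeSeries(np.stack([x, x], 1), TR), (0.01, 0.1))
        assert np.max(np.abs(ph.phases[:, 0] - ph.phases[:, 1])) < 1e-9

    def test_quarter_period_shift_gives_half_pi(self):
        f = 0.05
        t = np.arange(600) * TR
        x1 = np.cos(2 * np.pi * f * t)
        x2 = np.cos(2 * np.pi * f * (t - 1 / (4 * f)))
        ph = instantaneous_phase(RegionalTimeSeries(np.stack([x1, x2], 1), TR), (0.01, 0.1))
        diff = np.angle(np.exp(1j * (ph.phases[100:-100, 0] - ph.phases[100:-100, 1])))
        assert np.median(np.abs(diff)) == pytest.approx(np.pi / 2, abs=0.05)


class TestPhaseInteraction:
    def test_equal_phases_all_ones(self):
        ph = PhaseSeries(np.full((5, 4), 0.7), TR, (0.01, 0.1))
        np.testing.assert_allclose(phase_interaction_matrix(ph, 2), np.ones((4, 4)))

    def test_antiphase_pair(self):
        ph = PhaseSeries(np.array([[0.0, np.pi]]), TR, (0.01, 0.1))
        m = phase_interaction_matrix(ph, 0)
        assert m[0, 1] == pytest.approx(-1.0)

    def test_three_region_arithmetic(self):
        ph = PhaseSeries(np.array([[0.0, np.pi / 2, np.pi]]), TR, (0.01, 0.1))
        expected = np.array([[1, 0, -1], [0, 1, 0], [-1, 0, 1]], dtype=float)
        np.testing.assert_allclose(phase_interaction_matrix(ph, 0), expected, atol=1e-12)

    def test_out_of_range_index(self):
        ph = PhaseSeries(np.zeros((3, 2)), TR, (0.01, 0.1))
        with pytest.raises(InvalidInputError):
            phase_interaction_matrix(ph, 3)


class TestWindowedMean:
    def test_window_of_one_equals_instantaneous(self):
        rng = np.random.default_rng(3)
        ph = PhaseSeries(rng.uniform(-np.pi, np.pi, (10, 4)), TR, (0.01, 0.1))
        np.testing.assert_allclose(
            windowed_mean_interaction(ph, 5, 1), phase_interaction_matrix(ph, 5)
        )

    def test_alternating_offsets_average_to_zero(self):
        # region 1 alternates +pi/2 / -pi/2 relative to region 0
        phases = np.zeros((10, 2))
        phases[::2, 1] = np.pi / 2
        phases[1::2, 1] = -np.pi / 2
        ph = PhaseSeries(phases, TR, (0.01, 0.1))
        m = windowed_mean_interaction(ph, 0, 10)
        assert m[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_window_exceeding_series_raises(self):
        ph = PhaseSeries(np.zeros((5, 2)), TR, (0.01, 0.1))
        with pytest.raises(InvalidInputError):
            windowed_mean_interaction(ph, 2, 10)


class TestCosineSimilarity:
    def test_self_similarity_is_one(self):
        v = np.array([0.3, -1.2, 4.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        assert cosine_similarity([1, 2, 2], [2, 1, 2]) == pytest.approx(8 / 9)

    def test_zero_vector_raises(self):
        with pytest.raises(DegenerateInputError):
            cosine_similarity([0, 0], [1, 1])


class TestFCD:
    def test_stationary_dynamics_give_unit_matrix(self):
        t = np.arange(300) * TR
        rng = np.random.default_rng(0)
        base = np.cos(2 * np.pi * 0.05 * t)
        cols = [base + 0.001 * rng.normal(size=t.size) for _ in range(4)]
        d = fcd(RegionalTimeSeries(np.stack(cols, 1), TR))
        assert d.values.min() > 0.99

    def test_single_window_boundary(self):
        ts = RegionalTimeSeries(np.random.default_rng(1).normal(size=(30, 4)), TR)
        d = fcd(ts, window_length=30)
        assert d.n_windows == 1
        assert d.values.size == 0
        assert d.mean == 0.0

    def test_matches_brute_force_window_pairs(self, small_series):
        window, stride = 20, 3
        d = fcd(small_series, window, stride)
        ph = instantaneous_phase(small_series, (0.01, 0.1))
        iu = np.triu_indices(small_series.n_regions, 1)
        starts = range(0, small_series.n_samples - window + 1, stride)
        wins = [windowed_mean_interaction(ph, s, window)[iu] for s in starts]
        assert d.n_windows == len(wins)
        for i in range(len(wins)):
            for j in range(i + 1, len(wins)):
                assert d.matrix[i, j] == pytest.approx(
                    cosine_similarity(wins[i], wins[j]), abs=1e-10
                )

    def test_invariant_to_global_rescaling(self, small_series):
        d1 = fcd(small_series)
        scaled = RegionalTimeSeries(small_series.values * 11.0, small_series.tr)
        d2 = fcd(scaled)
        np.testing.assert_allclose(d1.matrix, d2.matrix, atol=1e-9)

    def test_matrix_invariants(self, small_series):
        d = fcd(small_series)
        assert np.all(np.abs(d.matrix) <= 1.0)
        np.testing.assert_allclose(np.diag(d.matrix), 1.0)
        np.testing.assert_allclose(d.matrix, d.matrix.T)

    def test_too_short_series_raises(self):
        ts = RegionalTimeSeries(np.random.default_rng(2).normal(size=(10, 3)), TR)
        with pytest.raises(InvalidInputError):
            fcd(ts, window_length=30)


class TestKSDistance:
    def test_identical_samples(self):
        s = [0.1, 0.4, 0.4, 0.9]
        assert ks_distance(s, s) == 0.0

    def test_disjoint_supports(self):
        assert ks_distance([1, 2, 3], [10, 11]) == 1.0

    def test_hand_worked_example(self):
        assert ks_distance([1, 2, 3], [2, 3, 4]) == pytest.approx(1 / 3)

    def test_empty_sample_raises(self):
        with pytest.raises(InvalidInputError):
            ks_distance([], [1.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-5, 5), min_size=1, max_size=15),
        st.lists(st.floats(-5, 5), min_size=1, max_size=15),
        st.lists(st.floats(-5, 5), min_size=1, max_size=15),
    )
    def test_matches_brute_force_and_metric_properties(self, s1, s2, s3):
        d12 = ks_distance(s1, s2)
        assert d12 == pytest.approx(brute_force_ks(s1, s2), abs=1e-12)
        assert d12 == pytest.approx(ks_distance(s2, s1), abs=1e-12)
        assert d12 <= ks_distance(s1, s3) + ks_distance(s3, s2) + 1e-12
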