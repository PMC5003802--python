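import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from brewcgh.segmentation import (
    call_segments,
    default_penalty,
    divergence_track,
    gene_sd,
    moving_average,
    segment_track,
    select_divergent_genes,
)


def brute_force_best_cost(x, penalty):
    """Exhaustive minimum of SSE + penalty * breakpoints over all segmentations."""
    n = len(x)
    best = np.inf
    for mask in itertools.product([0, 1], repeat=n - 1):
        bounds = [0] + [i + 1 for i, m in enumerate(mask) if m] + [n]
        cost = penalty * (len(bounds) - 2)
        for a, b in zip(bounds, bounds[1:]):
            seg = x[a:b]
            cost += float(np.sum((seg - seg.mean()) ** 2))
        best = min(best, cost)
    return best


def dp_cost(segset, x, penalty):
    cost = penalty * segset.n_breakpoints
    for s in segset.segments:
        seg = x[s.first : s.last + 1]
        cost += float(np.sum((seg - s.mean) ** 2))
    return cost


class TestSegmentTrack:
    def test_constant_track_single_segment(self):
        out = segment_track(np.full(10, 1.7), penalty=0.5)
        assert len(out.segments) == 1
        assert out.segments[0].mean == pytest.approx(1.7)

    def test_noiseless_step_found_exactly(self):
        x = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        out = segment_track(x, penalty=0.01)
        assert [(s.first, s.last) for s in out.segments] == [(0, 2), (3, 5)]
        assert [s.mean for s in out.segments] == pytest.approx([0.0, 1.0])

    def test_zero_penalty_prefers_fewest_segments(self):
        x = np.array([0, 0, 2, 2], dtype=float)
        out = segment_track(x, penalty=0.0)
        assert len(out.segments) == 2  # not four singletons

    def test_dp_equals_brute_force_on_random_tracks(self):
        rng = np.random.default_rng(13)
        for n in (2, 5, 9):
            x = np.round(rng.normal(size=n), 2)
            for penalty in (0.0, 0.1, 1.0):
                got = dp_cost(segment_track(x, penalty), x, penalty)
                assert got == pytest.approx(brute_force_best_cost(x, penalty), abs=1e-9)

    def test_huge_penalty_collapses_to_mean(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        out = segment_track(x, penalty=1e6)
        assert len(out.segments) == 1
        assert out.segments[0].mean == pytest.approx(x.mean())

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            segment_track([], 0.1)
        with pytest.raises(ValueError):
            segment_track([1.0], -0.1)

    def test_default_penalty_zero_for_noiseless(self):
        assert default_penalty(np.zeros(20)) == 0.0
        assert default_penalty(np.random.default_rng(0).normal(size=50)) > 0


class TestCallSegments:
    def test_threshold_rules(self):
        x = np.array([0.0] * 3 + [0.585] * 3 + [-6.0] * 3)
        segs = call_segments(segment_track(x, 0.01), 0.3, -0.3)
        assert [s.call for s in segs.segments] == ["neutral", "gain", "loss"]

    def test_malformed_thresholds(self):
        segs = segment_track([0.0, 0.0], 0.1)
        with pytest.raises(ValueError):
            call_segments(segs, -0.3, 0.3)


class TestDivergence:
    def test_identical_strains_zero_sd(self, small_matrix):
        m = small_matrix.with_data(
            pd.DataFrame({s: range(6) for s in "AB"},
                         index=small_matrix.data.index, dtype=float)
        )
        assert (gene_sd(m) == 0).all()

    def test_two_point_sample_sd(self, small_matrix):
        sd = gene_sd(small_matrix)
        # g2 has values (0, 1, -6): sample SD
        assert sd["g2"] == pytest.approx(np.std([0, 1, -6], ddof=1))

    def test_single_strain_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            gene_sd(small_matrix.with_data(small_matrix.data[["A"]]))

    def test_permutation_invariance(self, small_matrix):
        sd1 = gene_sd(small_matrix)
        perm = small_matrix.with_data(small_matrix.data[["C", "A", "B"]])
        pd.testing.assert_series_equal(sd1, gene_sd(perm))


class TestMovingAverage:
    def test_window_one_is_identity(self):
        x = np.array([3.0, 1.0, 4.0])
        np.testing.assert_array_equal(moving_average(x, 1), x)

    def test_constant_preserved(self):
        np.testing.assert_allclose(moving_average(np.full(7, 2.0), 5), 2.0)

    def test_hand_computed_example(self):
        out = moving_average(np.array([0.0, 0, 3, 0, 0]), 3)
        np.testing.assert_allclose(out, [0, 1, 1, 1, 0])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average(np.zeros(5), 4)

    @settings(deadline=None, derandomize=True)
    @given(
        hnp.arrays(float, st.integers(1, 40),
                   elements=st.floats(-10, 10, allow_nan=False)),
        st.sampled_from([1, 3, 5, 9]),
    )
    def test_bounded_by_input_range(self, x, w):
        out = moving_average(x, w)
        assert out.min() >= x.min() - 1e-9 and out.max() <= x.max() + 1e-9

    def test_smoothing_never_crosses_chromosomes(self, small_matrix):
        # chromosome II is constant across strains -> its smoothed SD stays 0
        # even though chromosome I carries a huge-SD gene next to the boundary
        track = divergence_track(small_matrix, window=3)
        assert (track.loc[track.chromosome == "II", "smoothed"] == 0).all()
        assert track.loc["g2", "sd"] > 1


class TestSelectDivergent:
    def test_quiet_matrix_selects_nothing(self, small_matrix):
        m = small_matrix.with_data(small_matrix.data.clip(-1, 1))
        assert select_divergent_genes(m) == set()

    def test_absent_gene_selected(self, small_matrix):
        assert "g2" in select_divergent_genes(small_matrix)

    def test_boundary_is_strict(self, small_matrix):
        data = small_matrix.data.copy() * 0
        data.loc["g0", "A"] = 2.0
        assert select_divergent_genes(small_matrix.with_data(data)) == set()
        data.loc["g0", "A"] = 2.0000001
        assert select_divergent_genes(small_matrix.with_data(data)) == {"g0"}

    def test_monotone_in_threshold(self, small_matrix):
        lo = select_divergent_genes(small_matrix, 1.0)
        hi = select_divergent_genes(small_matrix, 3.0)
        assert hi <= lo
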