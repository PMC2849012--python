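"""Group frequency heat maps and voxelwise binomial statistics."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mempattern import (
    HeatMap,
    InformationMap,
    aggregate_heat_map,
    binomial_tail,
    binomial_voxel_pvalues,
    resample_information_map,
    threshold_map,
)

GRID = (8, 8, 8)


def imap(voxels, subject_id=None):
    return InformationMap(
        selected=np.asarray(voxels, dtype=np.int64),
        n_select=len(voxels),
        roi_name="HC",
        grid_shape=GRID,
        subject_id=subject_id,
    )


class TestAggregateHeatMap:
    def test_ten_identical_maps_reach_frequency_ten(self):
        maps = [imap([(1, 2, 3), (4, 4, 4)], s) for s in range(10)]
        heat = aggregate_heat_map(maps)
        assert heat.counts[1, 2, 3] == 10
        assert heat.counts.max() == 10
        assert heat.n_subjects == 10

    def test_disjoint_maps_peak_at_one(self):
        maps = [imap([(s, 0, 0)]) for s in range(5)]
        heat = aggregate_heat_map(maps)
        assert heat.counts.max() == 1

    def test_total_count_conservation(self, rng):
        # counting oracle: the heat map sums to the total selected voxels
        maps = []
        total = 0
        for s in range(6):
            k = rng.integers(1, 20)
            idx = rng.choice(8 * 8 * 8, size=k, replace=False)
            vox = np.stack(np.unravel_index(idx, GRID), axis=1)
            maps.append(imap(vox, s))
            total += k
        heat = aggregate_heat_map(maps)
        assert heat.counts.sum() == total

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            aggregate_heat_map([])

    def test_grid_mismatch_raises(self):
        a = imap([(0, 0, 0)])
        b = InformationMap(
            selected=np.array([[0, 0, 0]]), n_select=1, roi_name="HC",
            grid_shape=(4, 4, 4),
        )
        with pytest.raises(ValueError, match="grid mismatch"):
            aggregate_heat_map([a, b])


class TestBinomialTail:
    def test_all_ten_subjects_under_half_null(self):
        assert binomial_tail(10, 10, 0.5) == pytest.approx(0.5**10, rel=1e-12)

    def test_zero_count_has_p_one(self):
        assert binomial_tail(0, 10, 0.1) == 1.0

    def test_matches_exact_fraction_enumeration(self):
        # term-by-term oracle in exact rational arithmetic
        p0 = Fraction(1, 10)
        expected = sum(
            comb(10, j) * p0**j * (1 - p0) ** (10 - j) for j in range(3, 11)
        )
        assert binomial_tail(3, 10, 0.1) == pytest.approx(float(expected), abs=1e-15)

    def test_agrees_with_scipy_sf_to_1e12(self):
        # independent library oracle over every n <= 20
        for n in range(1, 21):
            for p0 in (0.05, 0.2, 0.5, 0.9):
                for k in range(n + 1):
                    ours = binomial_tail(k, n, p0)
                    ref = stats.binom.sf(k - 1, n, p0)
                    assert ours == pytest.approx(ref, abs=1e-12), (k, n, p0)

    def test_monotone_nonincreasing_in_count(self):
        tails = [binomial_tail(k, 10, 0.3) for k in range(11)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))

    @settings(derandomize=True, max_examples=60)
    @given(
        n=st.integers(1, 20),
        k=st.integers(0, 20),
        p0=st.floats(0.01, 0.99),
    )
    def test_tail_is_a_probability_and_monotone_in_p0(self, n, k, p0):
        p = binomial_tail(k, n, p0)
        assert 0.0 <= p <= 1.0
        if k <= n:
            assert p <= binomial_tail(k, n, min(p0 + 0.2, 0.995)) + 1e-12

    def test_invalid_p0_raises(self):
        heat = HeatMap(counts=np.zeros(GRID, dtype=int), n_subjects=10)
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                binomial_voxel_pvalues(heat, bad)


class TestThresholdMap:
    def _pmap(self, counts, p0=0.2):
        heat = HeatMap(counts=counts, n_subjects=10)
        return binomial_voxel_pvalues(heat, p0)

    def test_alpha_near_one_keeps_everything_below_one(self):
        counts = np.zeros(GRID, dtype=int)
        counts[0, 0, 0] = 4
        pmap = self._pmap(counts)
        sig = threshold_map(pmap, 0.999999)
        assert [tuple(v) for v in sig] == [(0, 0, 0)]

    def test_alpha_below_minimum_tail_selects_nothing(self):
        counts = np.full(GRID, 10)
        pmap = self._pmap(counts, p0=0.5)
        assert len(threshold_map(pmap, 1e-5)) == 0  # min tail is 0.5^10 ~ 1e-3

    def test_bonferroni_tightens_threshold(self):
        counts = np.zeros(GRID, dtype=int)
        counts[1, 1, 1] = 6  # p ~ 6e-3 at p0=0.2
        pmap = self._pmap(counts)
        assert len(threshold_map(pmap, 0.01)) == 1
        assert len(threshold_map(pmap, 0.01, bonferroni=True, n_tests=100)) == 0

    def test_pvalues_monotone_in_frequency(self):
        counts = np.arange(11).reshape(11, 1, 1) * np.ones((11, 2, 2), dtype=int)
        heat = HeatMap(counts=counts.astype(int), n_subjects=10)
        pmap = binomial_voxel_pvalues(heat, 0.3)
        flat = pmap.p[:, 0, 0]
        assert np.all(np.diff(flat) <= 0)


class TestNullCalibration:
    def test_false_positive_rate_bounded_by_alpha(self):
        # independent random maps of fixed size: the fraction of voxels
        # reaching p < alpha stays near or below alpha (conservative test)
        rng = np.random.default_rng(0)
        n_sub, k, alpha = 10, 40, 0.01
        n_grid = 12 * 12 * 12
        maps = []
        for s in range(n_sub):
            idx = rng.choice(n_grid, size=k, replace=False)
            vox = np.stack(np.unravel_index(idx, (12, 12, 12)), axis=1)
            maps.append(
                InformationMap(
                    selected=vox, n_select=k, roi_name="x", grid_shape=(12, 12, 12)
                )
            )
        heat = aggregate_heat_map(maps)
        pmap = binomial_voxel_pvalues(heat, p0=k / n_grid)
        frac = np.mean(pmap.p < alpha)
        assert frac <= 2 * alpha


class TestResample:
    def test_identity_affine_roundtrip(self):
        m = imap([(1, 2, 3), (4, 5, 6)])
        out = resample_information_map(m, np.eye(4), np.eye(4), GRID)
        assert np.array_equal(out.selected, m.selected)

    def test_translation_shifts_indices(self):
        m = imap([(1, 2, 3)])
        src = np.eye(4)
        tgt = np.eye(4)
        tgt[:3, 3] = [-2.0, 0.0, 0.0]  # target origin shifted
        out = resample_information_map(m, src, tgt, GRID)
        assert [tuple(v) for v in out.selected] == [(3, 2, 3)]

    def test_out_of_grid_voxels_dropped(self):
        m = imap([(7, 7, 7)])
        tgt = np.eye(4)
        tgt[:3, 3] = [-4.0, 0.0, 0.0]  # shifts the voxel to x=11, off-grid
        out = resample_information_map(m, np.eye(4), tgt, (4, 8, 8))
        assert len(out.selected) == 0
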