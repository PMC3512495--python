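import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from margincad.nmse import (BlockGrid, FeatureMatrix, build_block_grid,
                            compute_nmse, nmse_feature_matrix, select_features,
                            ttest_rank)
from margincad.volume import (ActivationMask, BrainVolume, SubjectRecord,
                              compute_activation_mask, mean_control_volume,
                              normalize_intensity_spect)


def nmse_loop(f, g, center, hw):
    """Independent triple-loop reference for the block NMSE."""
    x, y, z = center
    num = den = 0.0
    for l in range(-hw, hw + 1):
        for m in range(-hw, hw + 1):
            for n in range(-hw, hw + 1):
                fv = f[x + l, y + m, z + n]
                gv = g[x + l, y + m, z + n]
                num += (fv - gv) ** 2
                den += fv ** 2
    return num / den


def mask_of(arr):
    return ActivationMask(mask=np.asarray(arr, dtype=bool), threshold_value=0.0)


class TestBlockGrid:
    def test_full_15_cube_side5_lattice(self):
        grid = build_block_grid(mask_of(np.ones((15, 15, 15))), side=5)
        assert len(grid) == 27
        expect = {(x, y, z) for x in (2, 7, 12) for y in (2, 7, 12)
                  for z in (2, 7, 12)}
        assert {tuple(c) for c in grid.centers} == expect

    def test_single_voxel_mask_lattice_membership(self):
        m = np.zeros((15, 15, 15), dtype=bool)
        m[7, 7, 7] = True          # a lattice center for side 5
        assert len(build_block_grid(mask_of(m), side=5)) == 1
        m2 = np.zeros((15, 15, 15), dtype=bool)
        m2[6, 7, 7] = True         # not on the lattice
        assert len(build_block_grid(mask_of(m2), side=5)) == 0

    def test_even_side_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            build_block_grid(mask_of(np.ones((10, 10, 10))), side=4)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_block_grid(mask_of(np.zeros((10, 10, 10))), side=5)

    def test_blocks_disjoint_and_in_bounds(self):
        grid = build_block_grid(mask_of(np.ones((17, 13, 11))), side=3)
        hw = grid.half_width
        seen = np.zeros((17, 13, 11), dtype=int)
        for c in grid.centers:
            seen[c[0] - hw:c[0] + hw + 1, c[1] - hw:c[1] + hw + 1,
                 c[2] - hw:c[2] + hw + 1] += 1
        assert seen.max() == 1


class TestComputeNmse:
    def test_identical_blocks_zero(self, rng):
        f = BrainVolume(rng.random((9, 9, 9)) + 0.1)
        assert compute_nmse(f, f, (4, 4, 4), 2) == 0.0

    def test_zero_subject_gives_one(self, rng):
        f = BrainVolume(rng.random((9, 9, 9)) + 0.1)
        g = BrainVolume(np.zeros((9, 9, 9)))
        assert compute_nmse(f, g, (4, 4, 4), 2) == pytest.approx(1.0)

    def test_doubled_subject_gives_one(self, rng):
        f = BrainVolume(rng.random((9, 9, 9)) + 0.1)
        g = BrainVolume(2.0 * f.data)
        assert compute_nmse(f, g, (4, 4, 4), 2) == pytest.approx(1.0, abs=1e-12)

    def test_matches_triple_loop_oracle(self, rng):
        f = BrainVolume(rng.random((11, 11, 11)))
        g = BrainVolume(rng.random((11, 11, 11)))
        got = compute_nmse(f, g, (5, 5, 5), 2)
        assert got == pytest.approx(nmse_loop(f.data, g.data, (5, 5, 5), 2),
                                    abs=1e-12)

    def test_degenerate_block_rejected(self):
        f = BrainVolume(np.zeros((9, 9, 9)))
        g = BrainVolume(np.ones((9, 9, 9)))
        with pytest.raises(ValueError, match="degenerate"):
            compute_nmse(f, g, (4, 4, 4), 2)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_offset_permutation_invariance(self, seed):
        # any axis flip/permutation of the block leaves the sums unchanged
        r = np.random.default_rng(seed)
        f = r.random((5, 5, 5)) + 0.1
        g = r.random((5, 5, 5))
        base = np.sum((f - g) ** 2) / np.sum(f ** 2)
        perm = tuple(r.permutation(3))
        fp, gp = np.transpose(f, perm)[::-1], np.transpose(g, perm)[::-1]
        assert np.sum((fp - gp) ** 2) / np.sum(fp ** 2) == pytest.approx(
            base, abs=1e-12)


class TestFeatureMatrix:
    def test_controls_equal_to_mean_give_zero(self, rng):
        f = BrainVolume(rng.random((10, 10, 10)) + 0.5)
        cohort = [SubjectRecord(f"c{i}", 0, f) for i in range(3)]
        grid = build_block_grid(mask_of(np.ones((10, 10, 10))), side=3)
        fm = nmse_feature_matrix(cohort, f, grid)
        np.testing.assert_array_equal(fm.values, 0.0)

    def test_single_subject_single_block_composition(self, rng):
        f = BrainVolume(rng.random((5, 5, 5)) + 0.5)
        g = BrainVolume(rng.random((5, 5, 5)))
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        grid = build_block_grid(mask_of(m), side=5)
        fm = nmse_feature_matrix([SubjectRecord("s", 1, g)], f, grid)
        assert fm.values.shape == (1, 1)
        assert fm.values[0, 0] == pytest.approx(
            compute_nmse(f, g, (2, 2, 2), 2), abs=1e-14)

    def test_phantom_ad_rows_exceed_ctrl_in_deficit_blocks(self, small_cohort):
        records, truth = small_cohort
        cohort = [SubjectRecord(r.subject_id, r.label,
                                normalize_intensity_spect(r.volume), r.severity)
                  for r in records]
        f = mean_control_volume(cohort)
        grid = build_block_grid(compute_activation_mask(f), side=5)
        fm = nmse_feature_matrix(cohort, f, grid)
        region = truth.region_voxels()
        hw = grid.half_width
        in_region = [j for j, c in enumerate(fm.feature_ids) if region[c]]
        assert in_region, "phantom must contain blocks centered in regions"
        ad = fm.values[fm.labels == 1][:, in_region].mean()
        ctrl = fm.values[fm.labels == 0][:, in_region].mean()
        assert ad > ctrl

    def test_all_degenerate_rejected(self):
        f = BrainVolume(np.zeros((5, 5, 5)))
        g = BrainVolume(np.ones((5, 5, 5)))
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        grid = build_block_grid(mask_of(m), side=5)
        with pytest.raises(ValueError, match="degenerate"):
            nmse_feature_matrix([SubjectRecord("s", 1, g)], f, grid)


class TestTtestRank:
    @staticmethod
    def fm(values, labels):
        values = np.asarray(values, dtype=float)
        return FeatureMatrix(values=values,
                             feature_ids=[(j, 0, 0) for j in range(values.shape[1])],
                             labels=np.asarray(labels))

    def test_textbook_pooled_t(self):
        # groups {1,2,3} vs {4,5,6}: |t| = 3 / (1·sqrt(2/3)) = 3.6742...
        fm = self.fm([[4], [5], [6], [1], [2], [3]], [1, 1, 1, 0, 0, 0])
        [score] = ttest_rank(fm, n_select=1)
        assert score.t_abs == pytest.approx(3.0 / np.sqrt(2.0 / 3.0), abs=1e-12)

    def test_identical_distributions_rank_last(self, rng):
        same = rng.random(8)
        values = np.column_stack([same, np.r_[rng.random(4) + 5, rng.random(4)]])
        fm = self.fm(values, [1, 1, 1, 1, 0, 0, 0, 0])
        # constant-across-classes column: not identical values per subject,
        # but equal class distributions give small |t|; the separated column wins
        scores = ttest_rank(fm, n_select=2)
        assert scores[0].center == (1, 0, 0)

    def test_zero_variance_conventions(self):
        fm = self.fm([[1.0, 1.0], [1.0, 1.0], [1.0, 2.0], [1.0, 2.0]],
                     [0, 0, 1, 1])
        scores = ttest_rank(fm, n_select=2)
        assert scores[0].center == (1, 0, 0) and scores[0].t_abs == np.inf
        assert scores[1].t_abs == 0.0

    def test_no_truncation_and_monotone_order(self, rng):
        values = rng.random((10, 7))
        fm = self.fm(values, [1] * 5 + [0] * 5)
        scores = ttest_rank(fm, n_select=7)
        assert len(scores) == 7
        t = [s.t_abs for s in scores]
        assert all(a >= b for a, b in zip(t, t[1:]))

    def test_n_select_too_large_rejected(self, rng):
        fm = self.fm(rng.random((6, 3)), [1, 1, 1, 0, 0, 0])
        with pytest.raises(ValueError, match="n_select"):
            ttest_rank(fm, n_select=4)

    def test_select_features_reorders_columns(self, rng):
        values = rng.random((6, 5))
        fm = self.fm(values, [1, 1, 1, 0, 0, 0])
        scores = ttest_rank(fm, n_select=3)
        sub = select_features(fm, scores)
        assert sub.n_features == 3
        assert sub.feature_ids == [s.center for s in scores]
        j = fm.feature_ids.index(scores[0].center)
        np.testing.assert_array_equal(sub.values[:, 0], fm.values[:, j])
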