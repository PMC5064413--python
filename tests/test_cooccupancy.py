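"""Occupancy matrix, PCA, correlations, CTCF partition and state profiles."""

import numpy as np
import pytest

from circuitscan import cooccupancy as co
from circuitscan.intervals import (
    GenomicInterval,
    RegionSet,
    UndefinedInputError,
    merge,
)
from conftest import coverage_mask, random_region_set


def _rs(name, *spans, chrom="chr1"):
    return RegionSet(name, [GenomicInterval(chrom, s, e) for s, e in spans])


class TestOccupancyMatrix:
    def test_overlapping_sets_share_one_union_region(self):
        m = co.build_occupancy_matrix([_rs("A", (0, 10)), _rs("B", (5, 15))])
        assert len(m.regions) == 1
        assert m.regions.intervals[0].end - m.regions.intervals[0].start == 15
        assert m.M.tolist() == [[1, 1]]

    def test_disjoint_sets_give_one_hot_rows(self):
        m = co.build_occupancy_matrix([_rs("A", (0, 10)), _rs("B", (20, 30))])
        assert m.M.tolist() == [[1, 0], [0, 1]]

    def test_fewer_than_two_sets_is_error(self):
        with pytest.raises(ValueError):
            co.build_occupancy_matrix([_rs("A", (0, 10))])

    def test_random_sets_match_brute_force(self):
        rng = np.random.default_rng(1)
        sets = [random_region_set(rng, 50, f"s{i}") for i in range(4)]
        m = co.build_occupancy_matrix(sets)
        assert (m.M.sum(axis=1) >= 1).all()
        for c, s in enumerate(sets):
            for r, iv in enumerate(m.regions):
                expected = any(iv.overlaps(x) for x in s)
                assert bool(m.M[r, c]) == expected


class TestPCA:
    def _random_matrix(self, seed=0, n=500, p=4):
        rng = np.random.default_rng(seed)
        M = (rng.random((n, p)) < 0.4).astype(np.uint8)
        M[M.sum(axis=1) == 0, 0] = 1  # every union region overlaps something
        regions = RegionSet(
            "u", [GenomicInterval("chr1", i * 10, i * 10 + 5) for i in range(n)],
            merged=True, _presorted=True,
        )
        return co.OccupancyMatrix(regions, [f"r{i}" for i in range(p)], M)

    def test_duplicate_columns_have_identical_coordinates(self):
        m = self._random_matrix(seed=2, p=3)
        m.M[:, 2] = m.M[:, 1]
        res = co.pca_regulators(m)
        assert np.allclose(res.variable_coords[1], res.variable_coords[2], atol=1e-9)

    def test_anticorrelated_columns_have_opposite_dim1_sign(self):
        m = self._random_matrix(seed=3, p=2)
        m.M[:, 1] = 1 - m.M[:, 0]
        res = co.pca_regulators(m)
        assert res.variable_coords[0, 0] * res.variable_coords[1, 0] < 0

    def test_scores_match_eigendecomposition_oracle(self):
        m = self._random_matrix(seed=4)
        res = co.pca_regulators(m)
        X = m.M.astype(float) - m.M.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(X.T, ddof=1))
        v1 = evecs[:, np.argmax(evals)]
        oracle = X @ v1
        got = res.region_scores[:, 0]
        agree = min(
            np.abs(got - oracle).max(), np.abs(got + oracle).max()
        )
        assert agree < 1e-8

    def test_reconstruction_with_all_components(self):
        m = self._random_matrix(seed=5)
        res = co.pca_regulators(m)
        X = m.M.astype(float) - m.M.mean(axis=0)
        # scores = U S, loadings rows of Vt: X = scores @ Vt
        _, _, Vt = np.linalg.svd(X, full_matrices=False)
        # use the returned scores and re-derived loadings (signs fixed jointly)
        recon = res.region_scores @ np.linalg.lstsq(res.region_scores, X, rcond=None)[0]
        assert np.abs(recon - X).max() < 1e-6

    def test_explained_sums_to_one_and_coords_bounded(self):
        res = co.pca_regulators(self._random_matrix(seed=6))
        assert res.explained.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.abs(res.variable_coords) <= 1.0 + 1e-12).all()

    def test_density_curves_peak_at_one(self):
        res = co.pca_regulators(self._random_matrix(seed=7))
        for curve in res.dim1_density.values():
            assert curve.max() == pytest.approx(1.0)

    def test_zero_variance_column_warns_and_zeroes(self):
        m = self._random_matrix(seed=8, p=3)
        m.M[:, 2] = 1
        with pytest.warns(UserWarning, match="zero variance"):
            res = co.pca_regulators(m)
        assert np.allclose(res.variable_coords[2], 0.0)


class TestCorrelation:
    def test_identical_and_complementary_columns(self):
        rng = np.random.default_rng(9)
        col = (rng.random(200) < 0.5).astype(np.uint8)
        M = np.stack([col, col, 1 - col], axis=1)
        regions = RegionSet(
            "u", [GenomicInterval("chr1", i * 10, i * 10 + 5) for i in range(200)],
            merged=True, _presorted=True,
        )
        m = co.OccupancyMatrix(regions, ["a", "b", "c"], M)
        assert co.regulator_correlation(m, "a", "b").R == pytest.approx(1.0)
        assert co.regulator_correlation(m, "a", "c").R == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(10)
        M = (rng.random((200, 2)) < 0.3).astype(np.uint8)
        M[0] = [1, 0]
        M[1] = [0, 1]  # guarantee variance
        regions = RegionSet(
            "u", [GenomicInterval("chr1", i * 10, i * 10 + 5) for i in range(200)],
            merged=True, _presorted=True,
        )
        m = co.OccupancyMatrix(regions, ["a", "b"], M)
        res = co.regulator_correlation(m, "a", "b")
        x, y = M[:, 0].astype(float), M[:, 1].astype(float)
        r_oracle = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert res.R == pytest.approx(r_oracle, abs=1e-12)
        # p from the t transform with n-2 dof
        from scipy import stats

        n = len(x)
        t = r_oracle * np.sqrt((n - 2) / (1 - r_oracle**2))
        p_oracle = 2 * stats.t.sf(abs(t), df=n - 2)
        assert res.p == pytest.approx(p_oracle, rel=1e-6)

    def test_zero_variance_is_error(self):
        regions = RegionSet(
            "u", [GenomicInterval("chr1", i * 10, i * 10 + 5) for i in range(10)],
            merged=True, _presorted=True,
        )
        m = co.OccupancyMatrix(
            regions, ["a", "b"], np.stack([np.ones(10), np.arange(10) % 2], axis=1)
        )
        with pytest.raises(UndefinedInputError):
            co.regulator_correlation(m, "a", "b")


class TestPartitionByCtcf:
    def test_toy_example(self):
        smc1a = _rs("SMC1A", (0, 10), (20, 30))
        ctcf = _rs("CTCF", (25, 28))
        w, n = co.partition_by_ctcf(smc1a, ctcf)
        assert [(iv.start, iv.end) for iv in w] == [(20, 30)]
        assert [(iv.start, iv.end) for iv in n] == [(0, 10)]

    def test_empty_ctcf(self):
        smc1a = _rs("SMC1A", (0, 10))
        w, n = co.partition_by_ctcf(smc1a, RegionSet("CTCF", []))
        assert len(w) == 0 and len(n) == 1

    def test_random_inputs_partition_exactly(self):
        rng = np.random.default_rng(21)
        smc1a = random_region_set(rng, 120, "SMC1A")
        ctcf = random_region_set(rng, 60, "CTCF")
        w, n = co.partition_by_ctcf(smc1a, ctcf)
        assert len(w) + len(n) == len(smc1a)
        assert sorted(w.intervals + n.intervals) == sorted(smc1a.intervals)
        for iv in w:
            assert any(iv.overlaps(c) for c in ctcf)
        for iv in n:
            assert not any(iv.overlaps(c) for c in ctcf)


class TestStateOverlap:
    def test_fully_inside_one_state(self):
        seg = [(GenomicInterval("chr1", 0, 1000), "1_TssA")]
        prof = co.state_overlap_profile(_rs("A", (100, 200)), seg)
        assert prof.ratios == {"1_TssA": 1.0}

    def test_straddling_two_equal_states(self):
        seg = [
            (GenomicInterval("chr1", 0, 100), "1_TssA"),
            (GenomicInterval("chr1", 100, 200), "9_EnhA1"),
        ]
        prof = co.state_overlap_profile(_rs("A", (50, 150)), seg)
        assert prof.ratios["1_TssA"] == pytest.approx(0.5)
        assert prof.ratios["9_EnhA1"] == pytest.approx(0.5)

    def test_unannotated_bases_counted(self):
        seg = [(GenomicInterval("chr1", 0, 100), "5_Tx")]
        prof = co.state_overlap_profile(_rs("A", (50, 150)), seg)
        assert prof.ratios[co.UNANNOTATED] == pytest.approx(0.5)

    def test_overlapping_segmentation_is_error(self):
        seg = [
            (GenomicInterval("chr1", 0, 100), "a"),
            (GenomicInterval("chr1", 50, 150), "b"),
        ]
        with pytest.raises(ValueError, match="overlapping"):
            co.state_overlap_profile(_rs("A", (0, 10)), seg)

    def test_random_tiling_matches_per_base_oracle(self):
        rng = np.random.default_rng(23)
        rs = merge(random_region_set(rng, 60, "A", chroms=("chr1",)))
        bounds = np.sort(rng.choice(np.arange(1, 1000), size=9, replace=False))
        bounds = [0, *bounds.tolist(), 1000]
        labels = [f"s{i % 3}" for i in range(len(bounds) - 1)]
        seg = [
            (GenomicInterval("chr1", s, e), lab)
            for s, e, lab in zip(bounds[:-1], bounds[1:], labels)
        ]
        prof = co.state_overlap_profile(rs, seg)
        mask = coverage_mask(rs, chroms=("chr1",))["chr1"]
        state_of_base = np.empty(1000, dtype=object)
        for (iv, lab) in seg:
            state_of_base[iv.start : iv.end] = lab
        total = mask.sum()
        for lab in set(labels):
            expected = np.sum(mask & (state_of_base == lab)) / total
            assert prof.ratios.get(lab, 0.0) == pytest.approx(expected)
        assert sum(prof.ratios.values()) == pytest.approx(1.0, abs=1e-9)


class TestColocalization:
    def test_identical_sets_all_ones(self):
        a = _rs("A", (0, 10), (20, 30))
        b = _rs("B", (0, 10), (20, 30))
        res = co.colocalization_matrix([a, b])
        assert np.allclose(res.F, 1.0)

    def test_duplicates_cluster_adjacent(self):
        rng = np.random.default_rng(31)
        s1 = random_region_set(rng, 50, "s1")
        s2 = RegionSet("s2", s1.intervals)  # duplicate
        s3 = random_region_set(rng, 50, "s3")
        s4 = random_region_set(rng, 50, "s4")
        res = co.colocalization_matrix([s1, s3, s2, s4])
        pos = {res.regulators[i]: res.order.index(i) for i in range(4)}
        assert abs(pos["s1"] - pos["s2"]) == 1

    def test_entries_match_overlap_fraction(self):
        from circuitscan.intervals import overlap_fraction

        rng = np.random.default_rng(33)
        sets = [random_region_set(rng, 40, f"s{i}") for i in range(5)]
        res = co.colocalization_matrix(sets)
        assert np.allclose(np.diag(res.F), 1.0)
        for i in range(5):
            for j in range(5):
                if i != j:
                    assert res.F[i, j] == pytest.approx(
                        overlap_fraction(sets[i], sets[j])
                    )
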