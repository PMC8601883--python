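import numpy as np
import pandas as pd
import pytest

from replidepth import (
    DistanceMatrix,
    TaxonTable,
    beta_dispersion,
    bray_curtis_distance,
    jaccard_distance,
    lcbd,
    outlier_count_test,
    pcoa,
)


def _table(counts, taxa=None, reps=None):
    counts = np.asarray(counts)
    taxa = taxa or [f"t{i}" for i in range(counts.shape[0])]
    reps = reps or [f"r{j}" for j in range(counts.shape[1])]
    return TaxonTable(taxa, reps, counts)


class TestJaccard:
    def test_set_arithmetic_example(self):
        # {a,b,c} vs {b,c,d}: 1 - 2/4
        t = _table([[1, 0], [1, 1], [1, 1], [0, 1]])
        assert jaccard_distance(t).values[0, 1] == pytest.approx(0.5)

    def test_identical_and_disjoint_columns(self):
        t = _table([[3, 3, 0], [1, 1, 0], [0, 0, 9]])
        D = jaccard_distance(t).values
        assert D[0, 1] == 0.0
        assert D[0, 2] == 1.0

    def test_invariant_to_count_magnitudes(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 4, size=(12, 5))
        t1 = _table(counts)
        scaled = counts.copy()
        scaled[:, 2] *= 17
        t2 = _table(scaled)
        assert np.allclose(jaccard_distance(t1).values, jaccard_distance(t2).values)

    def test_two_empty_columns_distance_zero(self):
        t = _table([[0, 0, 1]])
        D = jaccard_distance(t).values
        assert D[0, 1] == 0.0 and D[0, 2] == 1.0


class TestBrayCurtis:
    def test_disjoint_and_identical(self):
        t = _table([[2, 0], [0, 2]])
        assert bray_curtis_distance(t).values[0, 1] == 1.0
        t2 = _table([[2, 2], [1, 1]])
        assert bray_curtis_distance(t2).values[0, 1] == 0.0

    def test_hand_evaluated_formula(self):
        # equal-sum columns (2,2) vs (4,0): (2+2)/8 = 0.5
        t = _table([[2, 4], [2, 0]])
        assert bray_curtis_distance(t).values[0, 1] == pytest.approx(0.5)

    def test_unequal_sums_warn(self):
        t = _table([[5, 1], [0, 1]])
        with pytest.warns(UserWarning, match="rarefy"):
            bray_curtis_distance(t)

    def test_matches_scipy_oracle(self):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(3)
        counts = rng.integers(0, 20, size=(6, 6))
        D = bray_curtis_distance(_table(counts), warn_unequal=False).values
        ref = squareform(pdist(counts.T, metric="braycurtis"))
        assert np.allclose(D, ref, atol=1e-12)


class TestLcbd:
    def test_two_replicate_symmetry(self):
        res, ss, bd = lcbd(_table([[1, 0], [0, 1]]), n_perm=99, seed=0)
        assert [r.lcbd for r in res] == pytest.approx([0.5, 0.5])

    def test_sums_to_one_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            t = _table(rng.integers(0, 30, size=(8, 5)))
            res, ss, bd = lcbd(t, n_perm=19, seed=1)
            assert sum(r.lcbd for r in res) == pytest.approx(1.0, abs=1e-9)
            assert all(r.lcbd >= 0 for r in res)

    def test_untransformed_matches_variance_decomposition_oracle(self):
        counts = np.array([[4, 0, 1], [2, 2, 2], [0, 5, 1], [1, 1, 6]])
        res, ss_total, bd = lcbd(_table(counts), transform="none", n_perm=19, seed=0)
        Y = counts.T.astype(float)
        centred = Y - Y.mean(axis=0)
        ss_i = (centred**2).sum(axis=1)
        assert ss_total == pytest.approx(ss_i.sum())
        assert bd == pytest.approx(ss_i.sum() / 2)
        assert [r.lcbd for r in res] == pytest.approx(list(ss_i / ss_i.sum()))

    def test_degenerate_identical_replicates(self):
        res, ss, bd = lcbd(_table([[3, 3, 3], [1, 1, 1]]), n_perm=19, seed=0)
        assert ss == 0.0
        assert [r.lcbd for r in res] == pytest.approx([1 / 3] * 3)
        assert not any(r.outlier for r in res)

    def test_disjoint_replicate_is_detected_outlier(self):
        # 5 identical replicates plus one disjoint: the odd one carries the
        # largest LCBD and is flagged after Holm adjustment
        hits = 0
        for seed in range(5):
            counts = np.zeros((12, 6), dtype=int)
            counts[:8, :5] = 10
            counts[8:, 5] = 10
            res, _, _ = lcbd(_table(counts), n_perm=999, seed=seed)
            odd = res[5]
            assert odd.lcbd == max(r.lcbd for r in res)
            hits += odd.p_adj <= 0.05
        assert hits >= 4


class TestPcoa:
    def test_collinear_points_single_axis(self):
        D = DistanceMatrix(["a", "b", "c"], np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float))
        res = pcoa(D)
        assert (res.eigenvalues > 1e-9).sum() == 1
        axis = res.coordinates[:, 0]
        assert np.allclose(sorted(axis), [-1, 0, 1], atol=1e-9)

    def test_zero_distances(self):
        D = DistanceMatrix(["a", "b"], np.zeros((2, 2)))
        res = pcoa(D)
        assert np.allclose(res.eigenvalues, 0.0)

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 2))
        from scipy.spatial.distance import pdist, squareform

        D = DistanceMatrix([f"p{i}" for i in range(6)], squareform(pdist(pts)))
        res = pcoa(D)
        coords = res.positive_coordinates
        back = squareform(pdist(coords))
        assert np.allclose(back, D.values, atol=1e-9)

    def test_double_centred_matrix_reconstruction(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 3, size=(15, 6))
        D = jaccard_distance(_table(counts))
        res = pcoa(D)
        n = D.n
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D.values**2) @ J
        # coordinates are eigvec * sqrt(|lambda|), so B = sum sign(l) c c^T
        recon = np.zeros_like(B)
        for k, lam in enumerate(res.eigenvalues):
            c = res.coordinates[:, k]
            recon += np.sign(lam) * np.outer(c, c)
        assert np.max(np.abs(B - recon)) < 1e-9

    def test_agrees_with_skbio_oracle(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa as sk_pcoa

        rng = np.random.default_rng(9)
        pts = rng.normal(size=(6, 3))
        from scipy.spatial.distance import pdist, squareform

        Dm = squareform(pdist(pts))
        ours = pcoa(DistanceMatrix([f"p{i}" for i in range(6)], Dm))
        theirs = sk_pcoa(skbio.DistanceMatrix(Dm))
        ref = np.sort(np.asarray(theirs.eigvals))[::-1]
        assert np.allclose(ours.eigenvalues[:3], ref[:3], atol=1e-8)


class TestBetaDispersion:
    def _euclid(self, pts, labels=None):
        from scipy.spatial.distance import pdist, squareform

        labels = labels or [f"p{i}" for i in range(len(pts))]
        return DistanceMatrix(labels, squareform(pdist(np.asarray(pts, float))))

    def test_hand_geometry_degenerate_case(self):
        # two groups, each the same pair of points 2 apart: every distance
        # to the group median is 1 (x sqrt(2) bias factor); zero variance
        D = self._euclid([(0, 0), (2, 0), (0, 0), (2, 0)])
        res = beta_dispersion(D, ["g1", "g1", "g2", "g2"], n_perm=99, seed=0)
        assert np.allclose(res.distances, np.sqrt(2.0), atol=1e-6)
        assert res.f_statistic == 0.0
        assert res.p_parametric == 1.0 and res.p_permutation == 1.0

    def test_inflated_group_detected(self):
        rng = np.random.default_rng(0)
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            a = rng.normal(size=(10, 2))
            b = rng.normal(size=(10, 2)) * 3.0
            D = self._euclid(np.vstack([a, b]))
            groups = ["a"] * 10 + ["b"] * 10
            res = beta_dispersion(D, groups, n_perm=199, seed=seed)
            ok = res.group_means["b"] > res.group_means["a"]
            flagged = bool(res.tukey["reject"].astype(bool).any())
            hits += ok and flagged and res.p_permutation <= 0.05
        assert hits >= 4

    def test_singleton_group_excluded_with_warning(self):
        D = self._euclid(np.random.default_rng(1).normal(size=(7, 2)))
        groups = ["a"] * 3 + ["b"] * 3 + ["c"]
        with pytest.warns(UserWarning, match="singleton"):
            res = beta_dispersion(D, groups, n_perm=49, seed=0)
        assert set(res.group_means) == {"a", "b"}

    def test_invariant_to_added_constant_dimension(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(12, 2))
        pts3 = np.hstack([pts, np.full((12, 1), 5.0)])
        groups = ["a"] * 6 + ["b"] * 6
        r2 = beta_dispersion(self._euclid(pts), groups, n_perm=99, seed=1)
        r3 = beta_dispersion(self._euclid(pts3), groups, n_perm=99, seed=1)
        assert r3.f_statistic == pytest.approx(r2.f_statistic, rel=1e-8)
        assert np.allclose(r2.distances, r3.distances, atol=1e-8)

    def test_jaccard_input_uses_imaginary_correction(self, mini_experiment):
        _, table, meta, _ = mini_experiment
        sample = table.select_replicates(meta.sample_ids)
        D = jaccard_distance(sample)
        groups = {r: meta.extract_of(r) for r in sample.replicate_ids}
        res = beta_dispersion(D, groups, n_perm=49, seed=0)
        assert np.all(res.distances >= 0)
        assert np.isfinite(res.f_statistic)


class TestOutlierCountTest:
    def test_uniform_table_statistic_zero(self):
        stat, dof, p = outlier_count_test([[5, 5], [5, 5]])
        assert stat == 0.0 and p == 1.0 and dof == 1

    def test_yates_corrected_hand_value(self):
        stat, dof, p = outlier_count_test([[10, 0], [0, 10]])
        assert stat == pytest.approx(16.2)
        assert p < 0.001

    def test_identical_columns_larger_table(self):
        stat, dof, p = outlier_count_test([[2, 2, 2], [7, 7, 7]])
        assert stat == pytest.approx(0.0)
        assert dof == 2

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            outlier_count_test([[0, 0], [3, 4]])
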