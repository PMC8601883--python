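import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from replidepth import (
    alpha_indices,
    bootstrap_se,
    chao1_unseen,
    depth_contrast_tests,
    extrapolated_richness,
    interpolated_richness,
    iqr_outliers,
    richness_curve,
)


class TestAlphaIndices:
    def test_equal_abundance_closed_form(self):
        s, h, si = alpha_indices(np.array([10, 10, 10, 10]))
        assert s == 4
        assert h == pytest.approx(np.log(4))
        assert si == pytest.approx(0.75)

    def test_single_taxon(self):
        assert alpha_indices(np.array([7, 0, 0])) == (1, 0.0, 0.0)

    def test_hand_computed_uneven_column(self):
        p = np.array([0.4, 0.3, 0.2, 0.1])
        s, h, si = alpha_indices(np.array([4, 3, 2, 1]))
        assert s == 4
        assert h == pytest.approx(float(-(p * np.log(p)).sum()), abs=1e-12)
        assert si == pytest.approx(0.70)

    def test_empty_column(self):
        assert alpha_indices(np.array([0, 0])) == (0, 0.0, 0.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            alpha_indices(np.array([-1, 2]))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        col=st.lists(st.integers(0, 40), min_size=1, max_size=15).filter(
            lambda c: sum(c) > 0
        ),
        factor=st.integers(2, 7),
    )
    def test_invariance_under_permutation_and_scaling(self, col, factor):
        col = np.array(col)
        perm = np.random.default_rng(1).permutation(len(col))
        base = alpha_indices(col)
        assert alpha_indices(col[perm]) == pytest.approx(base)
        assert alpha_indices(col * factor) == pytest.approx(base)


class TestInterpolation:
    def test_boundary_identity(self):
        col = np.array([4, 3, 2, 1, 1])
        assert interpolated_richness(col, 11) == 5.0

    def test_singleton_closed_form(self):
        assert interpolated_richness(np.array([99, 1]), 10) == pytest.approx(1.1)

    def test_one_read_sees_one_taxon(self):
        assert interpolated_richness(np.array([5, 5, 5]), 1) == pytest.approx(1.0)

    def test_m_beyond_n_errors(self):
        with pytest.raises(ValueError, match="extrapolation"):
            interpolated_richness(np.array([5, 5]), 11)


class TestExtrapolation:
    def test_no_singletons_flat_curve(self):
        col = np.array([4, 3, 2, 2])
        for m_star in (0, 10, 10_000):
            s, s_hat = extrapolated_richness(col, m_star)
            assert s == 4.0 and s_hat == 4.0

    def test_chao1_worked_example(self):
        # n=11, S_obs=5, f1=2, f2=1: f0 = (10/11)*4/2 = 20/11
        col = np.array([4, 3, 2, 1, 1])
        assert chao1_unseen(col) == pytest.approx(20 / 11)
        _, s_hat = extrapolated_richness(col, 0)
        assert s_hat == pytest.approx(5 + 20 / 11)
        assert s_hat == pytest.approx(6.81818181, abs=1e-6)

    def test_continuity_at_reference_sample(self):
        col = np.array([4, 3, 2, 1, 1])
        assert extrapolated_richness(col, 0)[0] == interpolated_richness(col, 11)

    def test_monotone_approach_to_asymptote(self):
        col = np.array([4, 3, 2, 1, 1])
        n = col.sum()
        values = [extrapolated_richness(col, m)[0] for m in (0, n, 5 * n, 10 * n)]
        assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))
        s10n, s_hat = extrapolated_richness(col, 10 * n)
        assert s10n <= s_hat and s_hat - s10n < 0.05

    def test_curve_is_non_decreasing_and_anchored(self):
        col = np.array([30, 12, 5, 2, 1, 1, 1])
        curve = richness_curve(col, knots=40)
        assert curve["richness"].is_monotonic_increasing
        n = col.sum()
        at_n = curve[curve.m == n]
        if not at_n.empty:
            assert at_n["richness"].iloc[0] == pytest.approx(7.0)


class TestBootstrapSe:
    def test_single_taxon_has_zero_se(self):
        out = bootstrap_se(np.array([50]), [10, 50, 100], nboot=10, seed=0)
        assert np.allclose(out["se"], 0.0)

    def test_unseen_taxon_uncertainty_at_reference_depth(self):
        col = np.array([10, 5, 2, 1, 1, 1])
        n = col.sum()
        out = bootstrap_se(col, [n], nboot=50, seed=1)
        assert out["se"].iloc[0] > 0

    def test_seed_reproducibility_bit_identical(self):
        col = np.array([10, 5, 2, 1, 1])
        a = bootstrap_se(col, [5, 19, 30], nboot=25, seed=3)
        b = bootstrap_se(col, [5, 19, 30], nboot=25, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_ci_width_follows_se(self):
        col = np.array([10, 5, 2, 1, 1])
        out = bootstrap_se(col, [10, 38], nboot=30, conf=0.95, seed=2)
        half = (out["ci_upper"] - out["ci_lower"]) / 2
        assert np.allclose(half, 1.959964 * out["se"], rtol=1e-4)


class TestIqrOutliers:
    def test_worked_example(self):
        flags = iqr_outliers([10, 11, 12, 13, 50])
        assert list(flags) == [False, False, False, False, True]

    def test_all_equal_none_flagged(self):
        assert not iqr_outliers([3.0] * 6).any()

    def test_small_symmetric_sample_none_flagged(self):
        assert not iqr_outliers([1, 2, 3, 4]).any()

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            iqr_outliers([1, 2, 3])


class TestDepthContrasts:
    def _records(self, vals1, vals2, extract="E1"):
        rows = []
        for i, v in enumerate(vals1):
            rows.append((f"r{i}", extract, 1000, v, v, v))
        for i, v in enumerate(vals2):
            rows.append((f"r{i}", extract, 10000, v, v, v))
        return pd.DataFrame(
            rows,
            columns=["replicate_id", "extract_id", "depth", "observed", "shannon", "simpson"],
        )

    def test_identical_groups(self):
        rec = self._records([5, 6, 7], [5, 6, 7])
        out = depth_contrast_tests(rec, 1000, 10000)
        obs = out[out["index"] == "observed"].iloc[0]
        assert obs["t"] == 0.0 and obs["p"] == 1.0
        assert obs["fold_change"] == pytest.approx(1.0)

    def test_doubling_gives_fold_two(self):
        rng = np.random.default_rng(0)
        base = 10 + rng.normal(0, 0.01, size=6)
        rec = self._records(base, 2 * base)
        out = depth_contrast_tests(rec, 1000, 10000)
        obs = out[out["index"] == "observed"].iloc[0]
        assert obs["fold_change"] == pytest.approx(2.0, rel=1e-3)
        assert obs["p"] < 1e-6

    def test_dropouts_excluded_pairwise(self):
        rec = self._records([5, 6, 7, 8], [6, 7, 8])  # r3 missing at 10k
        out = depth_contrast_tests(rec, 1000, 10000)
        assert out[out["index"] == "observed"]["n"].iloc[0] == 3

    def test_small_groups_skipped(self):
        rec = self._records([5], [6])
        out = depth_contrast_tests(rec, 1000, 10000)
        assert out.empty
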