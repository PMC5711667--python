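"""INR binning, chi-squared homogeneity, sphericity, GG-ANOVA, paired t."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import ptinrline as ptl
from ptinrline.errors import DegenerateDesignError, ValidationError
from ptinrline.stats import orthonormal_contrasts

RAW_COLS = ["coaguchek_xs_inr", "utmb_stago_inr", "arup_stago_inr", "bcs_xp_inr"]


def _spherical_data(rng, n=60, k=4, scale=1.0):
    """Data whose contrast-transformed sample covariance is exactly
    proportional to the identity (whitened contrast scores)."""
    C = orthonormal_contrasts(k)
    Z = rng.normal(size=(n, k - 1))
    Z = Z - Z.mean(axis=0)
    L = np.linalg.cholesky(np.cov(Z, rowvar=False, ddof=1))
    Zw = scale * (Z @ np.linalg.inv(L).T)
    return Zw @ C.T + rng.normal(size=(n, 1))  # subject shifts are contrast-free


class TestBinning:
    @pytest.mark.parametrize(
        "column, expected",
        [
            ("coaguchek_xs_inr", (31, 42, 29, 11, 7)),
            ("utmb_stago_inr", (42, 58, 17, 3, 0)),
            ("arup_stago_inr", (38, 55, 21, 6, 0)),
            ("bcs_xp_inr", (32, 42, 27, 15, 3)),
        ],
    )
    def test_study_raw_columns_match_published_frequencies(
        self, study_df, column, expected
    ):
        counts = ptl.bin_inr(study_df[column].dropna())
        np.testing.assert_array_equal(counts, expected)

    def test_empty_input(self):
        np.testing.assert_array_equal(ptl.bin_inr([]), np.zeros(5, dtype=int))

    def test_edge_value_falls_in_upper_bin(self):
        np.testing.assert_array_equal(ptl.bin_inr([2.0]), [0, 1, 0, 0, 0])
        # 2-dp rounding happens before binning: 1.999 rounds up to 2.00
        np.testing.assert_array_equal(ptl.bin_inr([1.999]), [0, 1, 0, 0, 0])

    def test_unordered_edges_rejected(self):
        with pytest.raises(ValidationError):
            ptl.bin_inr([1.0], edges=[3, 2])

    @given(
        values=st.lists(st.floats(0.1, 12.0), max_size=60),
        edges=st.lists(
            st.floats(0.5, 11.5), min_size=1, max_size=6, unique=True
        ).map(sorted),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bins_partition_the_samples(self, values, edges):
        assert ptl.bin_inr(values, edges).sum() == len(values)


class TestChiSquared:
    def _random_table(self, rng):
        return ptl.ContingencyTable(
            ("a", "b", "c"), ("u", "v", "w", "x"),
            rng.integers(3, 60, size=(3, 4)),
        )

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(20):
            tab = self._random_table(rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = ptl.chi_squared_homogeneity(tab)
            ref = sps.chi2_contingency(tab.counts, correction=False)
            assert res.statistic == pytest.approx(ref.statistic)
            assert res.p_value == pytest.approx(ref.pvalue)
            assert res.df == ref.dof
            np.testing.assert_allclose(res.expected, ref.expected_freq)

    def test_identical_rows_give_zero_statistic(self):
        tab = ptl.ContingencyTable(("a", "b"), ("u", "v"), [[10, 20], [10, 20]])
        res = ptl.chi_squared_homogeneity(tab)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_invariant_under_permutation(self, rng):
        tab = self._random_table(rng)
        perm_rows = tab.counts[[2, 0, 1], :][:, [3, 1, 0, 2]]
        tab2 = ptl.ContingencyTable(tab.row_labels, tab.col_labels, perm_rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert ptl.chi_squared_homogeneity(tab).statistic == pytest.approx(
                ptl.chi_squared_homogeneity(tab2).statistic
            )

    def test_expected_conserves_margins(self, rng):
        tab = self._random_table(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ptl.chi_squared_homogeneity(tab)
        np.testing.assert_allclose(res.expected.sum(axis=1), tab.row_totals)
        np.testing.assert_allclose(res.expected.sum(axis=0), tab.col_totals)

    def test_empty_margin_rejected_and_droppable(self):
        tab = ptl.ContingencyTable(("a", "b"), ("u", "v", "w"),
                                   [[5, 0, 3], [4, 0, 6]])
        with pytest.raises(DegenerateDesignError):
            ptl.chi_squared_homogeneity(tab)
        res = ptl.chi_squared_homogeneity(tab.drop_empty_columns())
        assert res.df == 1

    def test_sparse_expected_cells_warn(self):
        tab = ptl.ContingencyTable(("a", "b"), ("u", "v"), [[2, 30], [3, 28]])
        with pytest.warns(UserWarning, match="below 5"):
            ptl.chi_squared_homogeneity(tab)


class TestMauchly:
    def test_whitened_contrasts_give_w_of_one(self, rng):
        res = ptl.mauchly_test(_spherical_data(rng))
        assert res.w_statistic == pytest.approx(1.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0, abs=1e-10)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        X = rng.normal(size=(40, 4)) @ rng.normal(size=(4, 4))
        spher = pg.sphericity(pd.DataFrame(X), method="mauchly")
        res = ptl.mauchly_test(X)
        assert res.w_statistic == pytest.approx(float(spher.W), rel=1e-9)
        assert res.p_value == pytest.approx(float(spher.pval), rel=1e-6)

    def test_invariant_to_contrast_basis(self, rng):
        X = rng.normal(size=(30, 5)) @ rng.normal(size=(5, 5))
        k = X.shape[1]
        helmert = orthonormal_contrasts(k)
        # a second orthonormal basis of the contrast space
        Q, _ = np.linalg.qr(rng.normal(size=(k - 1, k - 1)))
        other = helmert @ Q
        a = ptl.mauchly_test(X, contrasts=helmert)
        b = ptl.mauchly_test(X, contrasts=other)
        assert a.w_statistic == pytest.approx(b.w_statistic, rel=1e-10)
        assert ptl.gg_epsilon(X, contrasts=helmert) == pytest.approx(
            ptl.gg_epsilon(X, contrasts=other), rel=1e-10
        )

    def test_nominal_type_i_error_under_compound_symmetry(self):
        from ptinrline.validation import type_i_error_mauchly

        rate = type_i_error_mauchly(n_reps=1000, n=120, k=4, seed=3)
        assert 0.03 <= rate <= 0.07

    def test_study_raw_inr_sphericity_grossly_violated(self, study_df):
        X = study_df[RAW_COLS].dropna().to_numpy()
        res = ptl.mauchly_test(X)
        assert X.shape == (119, 4)
        assert res.df == 5
        # published: p = 6.17e-59; agreement asserted on the log10 scale
        assert np.log10(res.p_value) == pytest.approx(np.log10(6.17e-59), abs=1.0)


class TestGGEpsilon:
    def test_spherical_covariance_gives_one(self, rng):
        assert ptl.gg_epsilon(_spherical_data(rng)) == pytest.approx(1.0, abs=1e-10)

    def test_lower_bound_for_one_dominant_contrast(self, rng):
        k = 4
        C = orthonormal_contrasts(k)
        z = rng.normal(size=(80, 1)) * [1.0, 1e-8, 1e-8]
        X = z @ C.T
        assert ptl.gg_epsilon(X) == pytest.approx(1.0 / (k - 1), abs=1e-6)

    def test_matches_eigenvalue_formula_on_ar1(self, rng):
        rho, k, n = 0.9, 4, 200
        cov = rho ** np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        X = rng.multivariate_normal(np.zeros(k), cov, size=n)
        C = orthonormal_contrasts(k)
        lam = np.linalg.eigvalsh(C.T @ np.cov(X, rowvar=False, ddof=1) @ C)
        eps_eig = lam.sum() ** 2 / ((k - 1) * (lam**2).sum())
        assert ptl.gg_epsilon(X) == pytest.approx(eps_eig, rel=1e-12)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        X = rng.normal(size=(50, 4)) @ rng.normal(size=(4, 4))
        assert ptl.gg_epsilon(X) == pytest.approx(
            float(pg.epsilon(pd.DataFrame(X), correction="gg")), rel=1e-9
        )


class TestRmAnova:
    def test_identical_columns_give_zero_f(self, rng):
        col = rng.normal(size=(30, 1))
        X = np.repeat(col, 4, axis=1)
        res = ptl.rm_anova(X)
        assert res.f_statistic == 0.0
        assert res.p_gg == 1.0

    def test_sum_of_squares_decomposition(self, rng):
        X = rng.normal(size=(25, 4)) + rng.normal(size=(25, 1))
        n, k = X.shape
        grand = X.mean()
        ss_tot = ((X - grand) ** 2).sum()
        ss_cond = n * ((X.mean(0) - grand) ** 2).sum()
        ss_subj = k * ((X.mean(1) - grand) ** 2).sum()
        ss_err = ss_tot - ss_cond - ss_subj
        res = ptl.rm_anova(X)
        f_ref = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
        assert res.f_statistic == pytest.approx(f_ref, rel=1e-9)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        X = rng.normal(size=(20, 3)) + 0.3 * np.arange(3)
        long = pd.DataFrame({
            "y": X.ravel(),
            "cond": np.tile(np.arange(3), 20),
            "subj": np.repeat(np.arange(20), 3),
        })
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subj",
                          correction=True)
        res = ptl.rm_anova(X)
        assert res.f_statistic == pytest.approx(float(ref["F"][0]), rel=1e-9)
        assert res.p_uncorrected == pytest.approx(float(ref["p_unc"][0]), rel=1e-9)
        assert res.p_gg == pytest.approx(float(ref["p_GG_corr"][0]), rel=1e-6)
        assert res.gg_epsilon == pytest.approx(float(ref["eps"][0]), rel=1e-9)

    def test_gg_correction_increases_p_for_detectable_effects(self, rng):
        # deflating both dfs raises the p-value whenever F >= 1 (the regime
        # where the correction matters; for F < 1 the inequality can flip)
        X = rng.normal(size=(30, 4)) @ rng.normal(size=(4, 4)) + [0, 1.0, 0.5, 2.0]
        res = ptl.rm_anova(X)
        assert res.gg_epsilon < 1
        assert res.f_statistic > 1
        assert res.p_gg >= res.p_uncorrected

    def test_nominal_type_i_error_with_gg(self):
        from ptinrline.validation import type_i_error_rm_anova

        rate = type_i_error_rm_anova(n_reps=1000, n=120, k=4, seed=5)
        assert 0.03 <= rate <= 0.07

    def test_study_raw_inr_site_effect(self, study_df):
        X = study_df[RAW_COLS].dropna().to_numpy()
        res = ptl.rm_anova(X)
        assert res.n_complete == 119
        # published GG-corrected p: 3.52e-24, asserted on the log10 scale
        assert np.log10(res.p_gg) == pytest.approx(np.log10(3.52e-24), abs=1.5)


class TestPairedT:
    def test_identical_inputs(self):
        res = ptl.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == 0.0
        assert res.p_value == 1.0

    def test_antisymmetry(self, rng):
        x, y = rng.normal(size=(2, 30))
        assert ptl.paired_t(x, y).t_statistic == pytest.approx(
            -ptl.paired_t(y, x).t_statistic
        )

    def test_matches_scipy(self, rng):
        x, y = rng.normal(size=(2, 25))
        res = ptl.paired_t(x, y)
        ref = sps.ttest_rel(x, y)
        assert res.t_statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)
        assert res.df == res.n_pairs - 1 == 24

    def test_zero_variance_nonzero_mean(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            res = ptl.paired_t([1.0, 2.0, 3.0], [0.5, 1.5, 2.5])
        assert res.p_value == 0.0

    def test_study_xs_vs_bcs_raw(self, study_df):
        sub = study_df[["coaguchek_xs_inr", "bcs_xp_inr"]].dropna()
        res = ptl.paired_t(sub["coaguchek_xs_inr"], sub["bcs_xp_inr"])
        assert res.n_pairs == 119
        assert res.p_value == pytest.approx(0.08, abs=0.01)

    def test_p_display_floor(self):
        assert ptl.format_p(1e-20) == "<2e-16"
        assert ptl.format_p(0.08) == "0.08"
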