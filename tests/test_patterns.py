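"""Pattern matrices and PCA against an eigendecomposition oracle."""

import numpy as np
import pandas as pd
import pytest

from conftest import eig_pca
from riverflux import PatternPCA, build_category_matrix, build_site_matrix, pca
from riverflux.io import AnalyteRecord, AnalyteRegistry


def flows_frame(rows):
    df = pd.DataFrame(rows, columns=["site_code", "analyte", "month", "mass_flow_ug_s"])
    df["month"] = df["month"].map(lambda m: pd.Period(m, "M"))
    df["river"] = "R"
    return df


class TestMatrices:
    def test_site_matrix_sums_panel(self):
        df = flows_frame(
            [
                ("s1", "a", "2020-01", 1.0), ("s1", "b", "2020-01", 2.0),
                ("s1", "a", "2020-02", 3.0), ("s1", "b", "2020-02", 4.0),
                ("s2", "a", "2020-01", 5.0), ("s2", "b", "2020-01", 6.0),
                ("s2", "a", "2020-02", 7.0), ("s2", "b", "2020-02", 8.0),
            ]
        )
        m = build_site_matrix(df)
        assert m.shape == (2, 2)
        assert m.loc["s1"].tolist() == [3.0, 7.0]
        assert m.loc["s2"].tolist() == [11.0, 15.0]

    def test_single_analyte_row_equals_its_series(self):
        df = flows_frame([("s1", "a", "2020-01", 1.5), ("s1", "a", "2020-02", 2.5)])
        m = build_site_matrix(df)
        assert m.loc["s1"].tolist() == [1.5, 2.5]

    def test_unsampled_cells_zero_filled_with_completeness(self):
        df = flows_frame([("s1", "a", "2020-01", 1.0), ("s2", "a", "2020-02", 2.0)])
        m = build_site_matrix(df)
        assert m.loc["s1", pd.Period("2020-02", "M")] == 0.0
        comp = m.attrs["completeness"]
        assert comp.loc["s1", pd.Period("2020-02", "M")] == 0.0
        assert comp.loc["s1", pd.Period("2020-01", "M")] == 1.0

    def test_study_shapes_on_builtin_campaign(self, default_flows, default_campaign):
        dataset, _ = default_campaign
        months = dataset.calendar.campaign_months()
        site = build_site_matrix(default_flows, dataset.sites, months=months)
        cat = build_category_matrix(default_flows, dataset.analytes, months=months)
        assert site.shape == (12, 16)
        assert cat.shape == (8, 16)
        # Row order: Sava stations upstream→downstream, then Drava.
        assert list(site.index[:2]) == ["S|Jes", "S|Jnk"]

    def test_category_matrix_singleton(self):
        registry = AnalyteRegistry([AnalyteRecord("a", "DIUR", 0.5)])
        df = flows_frame([("s1", "a", "2020-01", 1.0), ("s2", "a", "2020-01", 2.0)])
        m = build_category_matrix(df, registry)
        assert m.shape == (1, 1)
        assert m.iloc[0, 0] == 3.0


class TestPatternPCA:
    def test_rank_one_matrix_fully_explained_by_pc1(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([2.0, 1.0, 5.0])
        res = pca(pd.DataFrame(np.outer(u, v)), n_components=2)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)
        assert res.explained_variance_fraction[1] == pytest.approx(0.0, abs=1e-12)

    def test_identical_rows_are_degenerate(self):
        X = pd.DataFrame(np.ones((4, 3)))
        with pytest.raises(ValueError, match="degenerate"):
            pca(X, n_components=2)

    def test_too_many_components_is_an_error(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 5)))
        with pytest.raises(ValueError, match="n_components"):
            pca(X, n_components=4)

    def test_hand_checked_three_by_three(self):
        """Explained fractions of [[2,0,0],[0,1,0],[0,0,0]] after centring,
        cross-checked by the eigendecomposition oracle."""
        X = pd.DataFrame([[2.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 0.0]])
        res = pca(X, n_components=2)
        ref_fractions, _ = eig_pca(X, n_components=2)
        np.testing.assert_allclose(
            res.explained_variance_fraction, ref_fractions[:2], atol=1e-12
        )

    @pytest.mark.parametrize("standardize", [False, True])
    def test_agrees_with_eigendecomposition_oracle(self, standardize):
        rng = np.random.default_rng(123)
        for _ in range(40):
            rows = int(rng.integers(3, 9))
            cols = int(rng.integers(2, 9))
            k = min(rows - 1, cols)
            X = pd.DataFrame(rng.normal(size=(rows, cols)) * 10 + 5)
            est = PatternPCA(n_components=k, standardize=standardize).fit(X)
            ref_fractions, ref_scores = eig_pca(X, n_components=k, standardize=standardize)
            np.testing.assert_allclose(
                est.explained_variance_ratio_, ref_fractions[:k], atol=1e-8
            )
            # Compare scores component-wise up to an overall sign (the two
            # routes may break near-ties in the orientation convention
            # differently), skipping numerically rank-deficient components.
            for j in range(k):
                if ref_fractions[j] < 1e-10:
                    continue
                ours = est.scores_.to_numpy()[:, j]
                sign = 1.0 if float(ours @ ref_scores[:, j]) >= 0 else -1.0
                np.testing.assert_allclose(ours, sign * ref_scores[:, j], atol=1e-7)

    def test_explained_fractions_sum_to_one_at_full_rank(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(6, 4)))
        est = PatternPCA(n_components=min(6 - 1, 4)).fit(X)
        assert est.explained_variance_ratio_.sum() == pytest.approx(1.0)
        assert (np.diff(est.explained_variance_ratio_) <= 1e-12).all()

    def test_sign_convention_and_determinism(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(7, 5)))
        a = PatternPCA(n_components=3).fit(X)
        b = PatternPCA(n_components=3).fit(X.copy())
        pd.testing.assert_frame_equal(a.scores_, b.scores_)
        for col in a.loadings_:
            load = a.loadings_[col]
            assert load.iloc[int(np.argmax(np.abs(load.to_numpy())))] > 0

    def test_row_permutation_permutes_scores(self):
        rng = np.random.default_rng(17)
        X = pd.DataFrame(rng.normal(size=(6, 5)), index=[f"r{i}" for i in range(6)])
        perm = ["r3", "r0", "r5", "r1", "r4", "r2"]
        a = PatternPCA(n_components=2).fit(X)
        b = PatternPCA(n_components=2).fit(X.loc[perm])
        pd.testing.assert_frame_equal(a.scores_.loc[perm], b.scores_, atol=1e-10)

    def test_transform_matches_fit_scores(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(5, 4)))
        est = PatternPCA(n_components=2).fit(X)
        pd.testing.assert_frame_equal(est.transform(X), est.scores_, atol=1e-10)

    def test_components_are_orthogonal(self):
        rng = np.random.default_rng(21)
        X = pd.DataFrame(rng.normal(size=(8, 6)))
        est = PatternPCA(n_components=4).fit(X)
        gram = est.components_ @ est.components_.T
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-10)

    def test_zero_variance_column_blocks_standardization(self):
        X = pd.DataFrame([[1.0, 2.0], [2.0, 2.0], [3.0, 2.0]])
        with pytest.raises(ValueError, match="zero-variance"):
            pca(X, n_components=1, standardize=True)

    def test_score_distances_are_euclidean(self):
        rng = np.random.default_rng(30)
        X = pd.DataFrame(rng.normal(size=(5, 4)))
        est = PatternPCA(n_components=2).fit(X)
        s = est.scores_.to_numpy()
        expected = np.linalg.norm(s[0] - s[1])
        assert est.score_distances_.iloc[0, 1] == pytest.approx(expected)
        assert np.allclose(est.score_distances_, est.score_distances_.T)
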