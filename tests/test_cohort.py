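import numpy as np
import pandas as pd
import pytest

from nccall.cohort import (
    PCAResult,
    assemble_score_matrix,
    assign_target_genes,
    embed_umap,
    group_score_test,
    groupwise_slope,
    pca_decompose,
    top_loading_sites,
)


def score_df(ids, scores):
    return pd.DataFrame({"interval_id": ids, "onco_score": scores})


UNIVERSE = ["chr1:0-100", "chr1:200-300", "chr2:0-100"]


class TestAssembleScoreMatrix:
    def test_exact_assembly_and_canonical_order(self):
        per = {
            "s2": score_df(UNIVERSE[::-1], [3.0, 2.0, 1.0]),
            "s1": score_df(UNIVERSE, [10.0, 20.0, 30.0]),
        }
        mat = assemble_score_matrix(per, UNIVERSE)
        assert mat.index.tolist() == ["s1", "s2"]
        assert mat.columns.tolist() == UNIVERSE
        assert mat.loc["s2"].tolist() == [1.0, 2.0, 3.0]

    def test_single_sample(self):
        mat = assemble_score_matrix({"s": score_df(UNIVERSE, [1, 2, 3])}, UNIVERSE)
        assert mat.shape == (1, 3)

    def test_missing_site_rejected(self):
        with pytest.raises(ValueError, match="unscored"):
            assemble_score_matrix({"s": score_df(UNIVERSE[:2], [1, 2])}, UNIVERSE)


class TestPCA:
    def test_rank_one_matrix(self):
        X = pd.DataFrame(
            np.outer([1.0, 2.0, 3.0], [4.0, 0.5, 2.0]),
            index=list("abc"), columns=UNIVERSE,
        )
        res = pca_decompose(X, 2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_two_by_two_identity_split(self):
        X = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"],
                         columns=UNIVERSE[:2])
        res = pca_decompose(X, 1)
        # centered matrix has a single contrast axis carrying all variance
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_reconstruction_with_all_components(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 10)),
                         index=[f"s{i}" for i in range(6)],
                         columns=[f"chr1:{i * 100}-{i * 100 + 50}" for i in range(10)])
        res = pca_decompose(X, 6)
        recon = res.sample_scores.to_numpy() @ res.loadings.to_numpy().T
        centered = X.to_numpy() - X.to_numpy().mean(axis=0)
        assert np.allclose(recon, centered, atol=1e-10)

    def test_sign_convention_largest_loading_positive(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 8)),
                         columns=[f"chr1:{i}-{i + 1}" for i in range(8)])
        res = pca_decompose(X, 3)
        for comp in res.loadings.columns:
            v = res.loadings[comp].to_numpy()
            assert v[np.abs(v).argmax()] > 0

    def test_too_many_components_rejected(self):
        X = pd.DataFrame(np.eye(2), columns=UNIVERSE[:2])
        with pytest.raises(ValueError, match="n_components"):
            pca_decompose(X, 3)


def fake_pca(loads, ids):
    return PCAResult(
        sample_scores=pd.DataFrame(),
        loadings=pd.DataFrame({"PC1": loads}, index=pd.Index(ids, name="interval_id")),
        explained_variance_ratio=np.array([1.0]),
    )


class TestTopLoadingSites:
    def test_floor_counts(self):
        ids = [f"chr1:{i * 10}-{i * 10 + 5}" for i in range(1692)]
        pca = fake_pca(np.linspace(1, 0, 1692), ids)
        assert len(top_loading_sites(pca, "PC1", 0.05)) == 84

    def test_small_set_floor(self):
        ids = [f"chr1:{i * 10}-{i * 10 + 5}" for i in range(20)]
        got = top_loading_sites(fake_pca(np.arange(20.0), ids), "PC1", 0.05)
        assert got == [ids[-1]]

    def test_tie_breaks_toward_lower_coordinate(self):
        ids = ["chr1:500-600", "chr1:100-200", "chr1:300-400", "chr1:700-800"]
        pca = fake_pca([1.0, 0.5, 0.5, 0.2], ids)
        got = top_loading_sites(pca, "PC1", 0.5)  # floor(2)
        assert got == ["chr1:500-600", "chr1:100-200"]

    def test_near_unit_fraction_returns_all_but_floor_loss(self):
        ids = [f"chr1:{i * 10}-{i * 10 + 5}" for i in range(10)]
        got = top_loading_sites(fake_pca(np.arange(10.0), ids), "PC1", 1 - 1e-9)
        assert len(got) == 9

    def test_zero_site_fraction_rejected(self):
        ids = [f"chr1:{i}-{i + 1}" for i in range(5)]
        with pytest.raises(ValueError, match="zero sites"):
            top_loading_sites(fake_pca(np.arange(5.0), ids), "PC1", 0.05)

    def test_invariant_to_column_permutation(self, rng):
        ids = [f"chr1:{i * 10}-{i * 10 + 5}" for i in range(40)]
        X = pd.DataFrame(rng.normal(size=(6, 40)), columns=ids)
        perm = rng.permutation(40)
        a = top_loading_sites(pca_decompose(X, 2), "PC1", 0.1)
        b = top_loading_sites(pca_decompose(X.iloc[:, perm], 2), "PC1", 0.1)
        assert a == b


class TestUMAP:
    def test_separated_groups_and_determinism(self, rng):
        from sklearn.metrics import silhouette_score

        a = rng.normal(0, 0.3, size=(6, 4)) + np.array([6, 0, 0, 0])
        b = rng.normal(0, 0.3, size=(6, 4)) - np.array([6, 0, 0, 0])
        scores = pd.DataFrame(np.vstack([a, b]), columns=["PC1", "PC2", "PC3", "PC4"],
                              index=[f"s{i}" for i in range(12)])
        pca = PCAResult(scores, pd.DataFrame(), np.full(4, 0.25))
        with pytest.warns(UserWarning, match="reducing"):
            e1 = embed_umap(pca, 4, seed=42)
            e2 = embed_umap(pca, 4, seed=42)
        assert np.allclose(e1.to_numpy(), e2.to_numpy())
        labels = [0] * 6 + [1] * 6
        assert silhouette_score(e1.to_numpy(), labels) > 0
        assert e1.attrs["params"]["seed"] == 42


ANNOT = pd.DataFrame(
    {
        "gene": ["GENEA", "GENEB"],
        "chrom": ["chr1", "chr1"],
        "start": [10_000, 50_000],
        "end": [20_000, 60_000],
        "strand": ["+", "-"],
    }
)


class TestAssignTargetGenes:
    def test_gene_body_overlap(self):
        genes, unassigned = assign_target_genes(["chr1:15000-15500"], ANNOT)
        assert genes == ["GENEA"] and unassigned == []

    def test_promoter_window_upstream_of_tss(self):
        # 1500 bp upstream of GENEA's + strand TSS (10000)
        genes, _ = assign_target_genes(["chr1:8400-8600"], ANNOT, promoter_window=2000)
        assert genes == ["GENEA"]
        # minus-strand gene: promoter extends beyond end
        genes, _ = assign_target_genes(["chr1:61000-61200"], ANNOT, promoter_window=2000)
        assert genes == ["GENEB"]

    def test_intergenic_site_unassigned(self):
        genes, unassigned = assign_target_genes(["chr1:30000-30100"], ANNOT)
        assert genes == [] and unassigned == ["chr1:30000-30100"]


class TestGroupwiseSlope:
    def test_collinear_points(self):
        pts = pd.DataFrame({"PC1": [0, 1, 2], "PC2": [1, 3, 5], "group": "g"})
        assert groupwise_slope(pts)["g"] == pytest.approx(2.0)

    def test_symmetric_cloud_slope_zero(self):
        pts = pd.DataFrame(
            {"PC1": [-1, -1, 1, 1], "PC2": [-1, 1, -1, 1], "group": "g"}
        )
        assert groupwise_slope(pts)["g"] == pytest.approx(0.0)

    def test_three_point_normal_equations(self):
        x, y = np.array([0.0, 1.0, 3.0]), np.array([1.0, 2.0, 2.0])
        expected = (len(x) * (x * y).sum() - x.sum() * y.sum()) / (
            len(x) * (x**2).sum() - x.sum() ** 2
        )
        pts = pd.DataFrame({"PC1": x, "PC2": y, "group": "g"})
        assert groupwise_slope(pts)["g"] == pytest.approx(expected)

    def test_small_group_skipped_with_warning(self):
        pts = pd.DataFrame({"PC1": [0, 1, 0], "PC2": [0, 1, 5], "group": ["a", "a", "b"]})
        with pytest.warns(UserWarning, match="skipped"):
            slopes = groupwise_slope(pts)
        assert "b" not in slopes.index


class TestGroupScoreTest:
    def test_identical_groups_not_significant(self):
        vals = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = pd.Series(["a"] * 3 + ["b"] * 3)
        res = group_score_test(vals, labels)
        assert res["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_separated_groups_significant(self, rng):
        vals = pd.Series(np.r_[rng.normal(0, 0.1, 5), rng.normal(10, 0.1, 5)])
        labels = pd.Series(["a"] * 5 + ["b"] * 5)
        assert group_score_test(vals, labels)["p_adj"].iloc[0] < 1e-6

    def test_bonferroni_over_three_pairs(self, rng):
        vals = pd.Series(rng.normal(size=9))
        labels = pd.Series(["a", "b", "c"] * 3)
        res = group_score_test(vals, labels)
        assert len(res) == 3
        assert np.allclose(res["p_adj"], np.minimum(res["p_raw"] * 3, 1.0))
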