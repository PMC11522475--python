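from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest

from nccall.switching import (
    differential_target_sites,
    foldchange_group_test,
    interval_signal_enrichment,
    paired_comparison,
    partition_specific_genes,
    signature_zscore_compare,
)


def scores(ids, score, called):
    return pd.DataFrame({"interval_id": ids, "onco_score": score, "called": called})


IDS = ["s1", "s2", "s3", "s4"]


class TestDifferentialTargetSites:
    def make_pair(self):
        a = scores(IDS, [30.0, 12.0, 25.0, 0.5], [True, True, True, False])
        b = scores(IDS, [1.0, 2.0, 24.0, 20.0], [False, False, True, True])
        return paired_comparison(a, b)

    def test_call_discordance_and_delta_ranking(self):
        a_spec, b_spec = differential_target_sites(self.make_pair())
        assert a_spec["interval_id"].tolist() == ["s1", "s2"]  # deltas 29, 10
        assert b_spec["interval_id"].tolist() == ["s4"]
        # called in both -> neither set
        assert "s3" not in set(a_spec["interval_id"]) | set(b_spec["interval_id"])

    def test_top_k_truncates_after_ranking(self):
        a_spec, _ = differential_target_sites(self.make_pair(), top_k=1)
        assert a_spec["interval_id"].tolist() == ["s1"]

    def test_antisymmetry(self):
        pair = self.make_pair()
        swapped = pair.rename(
            columns={"onco_score_a": "onco_score_b", "onco_score_b": "onco_score_a",
                     "called_a": "called_b", "called_b": "called_a"}
        )
        swapped["delta"] = -swapped["delta"]
        a1, b1 = differential_target_sites(pair)
        b2, a2 = differential_target_sites(swapped)
        assert a1["interval_id"].tolist() == a2["interval_id"].tolist()
        assert b1["interval_id"].tolist() == b2["interval_id"].tolist()

    def test_disjoint_universes_rejected(self):
        a = scores(IDS, [1] * 4, [False] * 4)
        b = scores(["x1"] + IDS[1:], [1] * 4, [False] * 4)
        with pytest.raises(ValueError, match="universe"):
            paired_comparison(a, b)

    def test_no_called_sites_warns(self):
        a = scores(IDS, [0.0] * 4, [False] * 4)
        pair = paired_comparison(a, a)
        with pytest.warns(UserWarning, match="no called sites"):
            differential_target_sites(pair)


class TestPartitionSpecificGenes:
    def test_set_arithmetic(self):
        overl, non = partition_specific_genes(
            ["g1", "g2", "g3", "g4", "g5"], ["g1", "g2", "g3", "g4"]
        )
        assert non == {"G5"} and len(overl) == 4

    def test_disjoint_and_subset_cases(self):
        assert partition_specific_genes(["a", "b"], ["c"]) == (set(), {"A", "B"})
        assert partition_specific_genes(["a"], ["a", "b"]) == ({"A"}, set())

    def test_counts_conserve(self):
        spec = [f"g{i}" for i in range(30)]
        other = [f"g{i}" for i in range(10, 50)]
        overl, non = partition_specific_genes(spec, other)
        assert len(overl) + len(non) == 30


def exact_signed_rank_p(diffs, alternative="greater"):
    """Enumerate all 2^n sign assignments of |d| ranks (no ties/zeros)."""
    d = np.asarray(diffs, float)
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    ws = [np.sum([r for r, s in zip(ranks, signs) if s]) for signs in
          product([True, False], repeat=len(d))]
    ws = np.array(ws)
    if alternative == "greater":
        return np.mean(ws >= w_obs)
    raise NotImplementedError


class TestSignatureZscore:
    def make_expr(self, rng):
        cols = [f"{ph}{i}" for i in range(1, 7) for ph in "AB"]
        expr = pd.DataFrame(
            rng.lognormal(3, 1, size=(4, 12)), index=["G1", "G2", "G3", "CONST"],
            columns=cols,
        )
        expr.loc["CONST"] = 7.0
        return expr, [(f"A{i}", f"B{i}") for i in range(1, 7)]

    def test_zero_variance_gene_scores_zero(self, rng):
        expr, pairing = self.make_expr(rng)
        with pytest.warns(UserWarning, match="zero-variance"):
            res = signature_zscore_compare(expr, ["G1", "CONST"], pairing)
        assert (res["per_gene_z"].loc["CONST"] == 0).all()

    def test_per_gene_z_is_standardized(self, rng):
        expr, pairing = self.make_expr(rng)
        res = signature_zscore_compare(expr, ["G1", "G2", "G3"], pairing)
        z = res["per_gene_z"]
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=0), 1, atol=1e-12)

    def test_five_positive_pairs_exact_p(self):
        # 5 genes, every per-gene phase difference positive -> p = 1/2^5
        cols = ["A1", "B1", "A2", "B2"]
        base = np.array([[5.0, 1.0, 6.0, 2.0]])
        expr = pd.DataFrame(
            base + np.arange(5)[:, None] + np.linspace(0, 0.3, 4),
            index=[f"G{i}" for i in range(5)], columns=cols,
        )
        res = signature_zscore_compare(expr, list(expr.index), [("A1", "B1"), ("A2", "B2")])
        assert res["n"] == 5
        assert res["p"] == pytest.approx(1 / 32)
        assert res["p"] == pytest.approx(exact_signed_rank_p(res["diffs"]))

    def test_single_gene_program_value_equals_gene_z(self, rng):
        expr, pairing = self.make_expr(rng)
        res = signature_zscore_compare(expr, ["G2"], pairing)
        z = res["per_gene_z"].loc["G2"]
        assert np.allclose(res["sample_scores"].to_numpy(), z.to_numpy())

    def test_absent_program_rejected(self, rng):
        expr, pairing = self.make_expr(rng)
        with pytest.raises(ValueError, match="no program gene"):
            signature_zscore_compare(expr, ["NOPE"], pairing)


def exact_mwu_two_sided_p(x, y):
    """Enumerate all label assignments of the pooled sample (no ties)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(1 for xi in x for yi in y if xi > yi)
    n1n2 = n1 * len(y)
    us = []
    for idx in combinations(range(len(pooled)), n1):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        us.append(sum(1 for xi in xs for yi in ys if xi > yi))
    us = np.array(us)
    hi = max(u_obs, n1n2 - u_obs)
    return np.mean((us >= hi) | (us <= n1n2 - hi))


class TestIntervalSignalEnrichment:
    def test_complete_separation_exact_p(self):
        sig = pd.Series(
            np.r_[np.arange(10, 15), np.arange(5)],
            index=[f"t{i}" for i in range(5)] + [f"c{i}" for i in range(5)],
        )
        res = interval_signal_enrichment(
            sig, {"prog": [f"t{i}" for i in range(5)]}, [f"c{i}" for i in range(5)]
        )
        assert res["U"].iloc[0] == 25
        assert res["p_raw"].iloc[0] == pytest.approx(2 / 252)
        assert res["p_raw"].iloc[0] == pytest.approx(
            exact_mwu_two_sided_p(sig.iloc[:5].to_numpy(), sig.iloc[5:].to_numpy())
        )

    def test_exchangeable_set_not_significant(self, rng):
        vals = rng.normal(size=60)
        ids = [f"i{k}" for k in range(60)]
        sig = pd.Series(vals, index=ids)
        res = interval_signal_enrichment(sig, {"prog": ids[:20]}, ids[20:])
        assert res["p_raw"].iloc[0] > 0.05

    def test_bonferroni_over_two_sets(self, rng):
        sig = pd.Series(rng.normal(size=40), index=[f"i{k}" for k in range(40)])
        res = interval_signal_enrichment(
            sig, {"a": [f"i{k}" for k in range(10)], "b": [f"i{k}" for k in range(10, 20)]},
            [f"i{k}" for k in range(20, 40)],
        )
        assert np.allclose(res["p_adj"], np.minimum(res["p_raw"] * 2, 1.0))

    def test_control_overlap_rejected(self, rng):
        sig = pd.Series(rng.normal(size=10), index=[f"i{k}" for k in range(10)])
        with pytest.raises(ValueError, match="overlaps the control"):
            interval_signal_enrichment(sig, {"a": ["i0", "i1"]}, ["i1", "i2"])

    def test_empty_set_skipped_with_warning(self, rng):
        sig = pd.Series(rng.normal(size=10), index=[f"i{k}" for k in range(10)])
        with pytest.warns(UserWarning, match="empty"):
            res = interval_signal_enrichment(sig, {"a": ["zz"]}, ["i1", "i2"])
        assert len(res) == 0


class TestFoldchangeGroupTest:
    def test_identical_distributions(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = foldchange_group_test(x, x)
        assert res["p"] == pytest.approx(1.0)

    def test_one_sided_strong_separation(self, rng):
        a = rng.normal(2, 0.1, 30)
        b = rng.normal(-2, 0.1, 30)
        assert foldchange_group_test(a, b, alternative="greater")["p"] < 1e-12

    def test_direction_opposite_to_hypothesis(self, rng):
        a = rng.normal(-2, 0.1, 30)
        b = rng.normal(2, 0.1, 30)
        assert foldchange_group_test(a, b, alternative="greater")["p"] > 0.5

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match=">=2 genes"):
            foldchange_group_test([1.0], [1.0, 2.0])
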