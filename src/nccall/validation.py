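"""Self-contained synthetic benchmarks of the full pipeline.

Each function regenerates its inputs from a seed, runs the relevant pipeline
stages end to end, and returns summary metrics: Monte-Carlo agreement with
the analytic Dirichlet log-expectation, null calibration of site calling,
sensitivity/precision and fold monotonicity on planted enrichment, exactness
of the BH step, PCA program recovery on a two-group cohort, and exact
small-sample test values. These are the package's reference checks; the
study conditions (depths, site counts, folds, oncoprotein levels) are fixed
here and documented in the methods note.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import psi

from .cohort import assemble_score_matrix, pca_decompose, top_loading_sites
from .genomic_io import count_bp_overlap
from .model import ModelConfig, average_oncoprotein_score, bh_adjust, score_sample, substream
from .simulate import SimConfig, simulate_cohort, simulate_sample
from .switching import interval_signal_enrichment, signature_zscore_compare

LN2 = np.log(2)

#: cohort study conditions: two lineage-like groups with disjoint 40-site
#: programs inside an 800-site universe (top-5% = 40 sites). The two groups
#: span asymmetric oncoprotein-level ranges so that the principal axes align
#: with the programs (PC1 = between-group contrast dominated by the stronger
#: program, PC2 = the weaker program) instead of the symmetric sum/contrast
#: pair; see the methods note for the variance analysis.
COHORT_LAMBDAS = {"groupA": [0.6, 1.0, 1.5, 2.0], "groupB": [0.2, 0.3, 0.4, 0.5]}
#: cohort sequencing depth: deep enough that C-track count noise at depleted
#: oncoprotein sites does not blur the PC2 loading gap between programs.
COHORT_DEPTH = 1_000_000


def _score_planted_sample(sim, config: ModelConfig) -> pd.DataFrame:
    sites = sim.sites[sim.sites["class"] != "igg_artifact"].reset_index(drop=True)
    counts = pd.DataFrame(
        {
            "interval_id": sites["id"].to_numpy(),
            "bp_n": count_bp_overlap(sim.fragments_n, sites).to_numpy(),
            "bp_c": count_bp_overlap(sim.fragments_c, sites).to_numpy(),
        }
    )
    return score_sample(counts, config, sim.sample_id)


def closed_form_mu(bp_n, bp_c, prior: float = 1.0) -> np.ndarray:
    """Analytic posterior mean of the N/C score via the digamma identity."""
    an = np.asarray(bp_n, float) + prior
    ac = np.asarray(bp_c, float) + prior
    return (psi(an) - psi(an.sum()) - psi(ac) + psi(ac.sum())) / LN2


def closed_form_agreement(seed: int, n_intervals: int = 200) -> dict:
    """Fraction of intervals whose Monte-Carlo mu matches the closed form
    within 4 standard errors (4 * sd / sqrt(n_draws))."""
    rng = substream(seed, "bench", "closed-form")
    bp_n = rng.integers(0, 20_000, size=n_intervals)
    bp_c = rng.integers(0, 20_000, size=n_intervals)
    counts = pd.DataFrame(
        {"interval_id": [f"i{k}" for k in range(n_intervals)], "bp_n": bp_n, "bp_c": bp_c}
    )
    config = ModelConfig(seed=seed)
    res = score_sample(counts, config, "bench")
    oracle = closed_form_mu(bp_n, bp_c, config.prior_pseudocount)
    se = res["sd"].to_numpy() / np.sqrt(config.n_draws)
    agree = np.abs(res["mu"].to_numpy() - oracle) < 4 * se
    return {"agreement_fraction": float(agree.mean()), "n": n_intervals}


def null_calibration(seed: int, n_sites: int = 1000, depth: int = 200_000) -> dict:
    """Called sites on a zero-oncoprotein-level sample (should be ~none)."""
    cfg = SimConfig(
        genome=(("chr1", 5_000_000),), n_wt_sites=n_sites - 50, n_onco_sites=50,
        oncoprotein_level=0.0, depth=depth, igg_artifacts=0, seed=seed,
    )
    scores = _score_planted_sample(simulate_sample(cfg, "null"), ModelConfig(seed=seed))
    return {"called": int(scores["called"].sum()), "n": n_sites}


def sensitivity_recovery(
    seed: int, folds=(1.0, 2.0, 4.0, 8.0), depth: int = 200_000
) -> dict:
    """Planted-site recovery at 8-fold enrichment (50 of 250 sites) and
    monotonicity of the mean planted-site score across folds."""
    mean_scores = []
    sens = prec = float("nan")
    for fold in folds:
        cfg = SimConfig(
            n_wt_sites=200, n_onco_sites=50, onco_fold=fold, oncoprotein_level=1.0,
            depth=depth, igg_artifacts=0, seed=seed,
        )
        sim = simulate_sample(cfg, f"fold{fold:g}")
        scores = _score_planted_sample(sim, ModelConfig(seed=seed))
        merged = scores.merge(sim.truth, left_on="interval_id", right_on="site_id")
        onco = (merged["class"] == "oncoprotein").to_numpy()
        mean_scores.append(float(merged.loc[onco, "onco_score"].mean()))
        if fold == max(folds):
            tp = int((merged["called"] & onco).sum())
            fp = int((merged["called"] & ~onco).sum())
            sens = tp / int(onco.sum())
            prec = tp / (tp + fp) if tp + fp else 1.0
    rho = stats.spearmanr(folds, mean_scores).statistic
    return {
        "sensitivity": sens, "precision": prec, "fold_spearman": float(rho),
        "mean_scores_by_fold": dict(zip([f"{f:g}" for f in folds], mean_scores)),
        "n_planted": 50,
    }


def brute_force_bh(p) -> np.ndarray:
    """Independent step-up enumeration: q_(i) = min_{j>=i} p_(j) m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for j in range(m - 1, -1, -1):
        running = min(running, p[order[j]] * m / (j + 1))
        q[order[j]] = running
    return q


def bh_agreement(seed: int, n_vectors: int = 1000) -> dict:
    """Fraction of random p-vectors on which bh_adjust equals brute force."""
    rng = substream(seed, "bench", "bh")
    exact = 0
    for _ in range(n_vectors):
        n = int(rng.integers(1, 60))
        p = rng.uniform(size=n)
        p[rng.random(n) < 0.3] *= 1e-6  # mix in small p-values
        if np.allclose(bh_adjust(p), brute_force_bh(p), rtol=0, atol=1e-12):
            exact += 1
    return {"agreement_fraction": exact / n_vectors, "n": n_vectors}


def cohort_recovery(seed: int, depth: int = COHORT_DEPTH) -> dict:
    """Two-group cohort: top-5% PC1/PC2 loading sets vs planted programs
    (best-match Jaccard) and Spearman of oncoprotein level vs average score."""
    cfg = SimConfig(
        genome=(("chr1", 5_000_000),), n_wt_sites=720, n_onco_sites=0,
        depth=depth, igg_artifacts=0, seed=seed,
    )
    samples, sample_truth, site_truth = simulate_cohort(
        cfg, COHORT_LAMBDAS, n_onco_per_group=40
    )
    config = ModelConfig(seed=seed)
    per_sample = {sid: _score_planted_sample(s, config) for sid, s in samples.items()}
    universe = list(site_truth["site_id"])
    matrix = assemble_score_matrix(per_sample, universe)
    pca = pca_decompose(matrix, 4)
    programs = {
        g: set(site_truth.loc[site_truth["class"] == f"program:{g}", "site_id"])
        for g in COHORT_LAMBDAS
    }

    def best_jaccard(ids):
        s = set(ids)
        return max(
            (len(s & p) / len(s | p), g) for g, p in programs.items()
        )

    j1, g1 = best_jaccard(top_loading_sites(pca, "PC1", 0.05))
    j2, g2 = best_jaccard(top_loading_sites(pca, "PC2", 0.05))
    avg = {sid: average_oncoprotein_score(sc) for sid, sc in per_sample.items()}
    truth = sample_truth.set_index("sample_id")
    lam = truth["lambda"].astype(float)
    rho = stats.spearmanr(
        lam.to_numpy(), np.array([avg[s] for s in truth.index])
    ).statistic
    return {
        "pc1_jaccard": j1, "pc2_jaccard": j2,
        "pc1_program": g1, "pc2_program": g2,
        "lambda_score_spearman": float(rho),
        "explained_variance_ratio": pca.explained_variance_ratio.tolist(),
        "n_samples": len(samples), "n_sites": len(universe),
    }


def exact_small_sample_stats() -> dict:
    """Exact small-n test values through the package's statistical paths:
    one-sided signed-rank with five concordant pairs and a two-sided
    Mann-Whitney U with complete separation at n1 = n2 = 5."""
    # five genes, two sample pairs, every per-gene phase difference positive
    rows = [[10 + 3 * i, 1 + i, 8 + 2 * i, 2] for i in range(5)]
    expr = pd.DataFrame(
        rows, index=[f"G{i}" for i in range(5)], columns=["A1", "B1", "A2", "B2"],
        dtype=float,
    )
    wres = signature_zscore_compare(
        expr, list(expr.index), [("A1", "B1"), ("A2", "B2")], alternative="greater"
    )
    sig = pd.Series(
        np.r_[np.arange(10.0, 15.0), np.arange(5.0)],
        index=[f"t{i}" for i in range(5)] + [f"c{i}" for i in range(5)],
    )
    mres = interval_signal_enrichment(
        sig, {"set": [f"t{i}" for i in range(5)]}, [f"c{i}" for i in range(5)]
    )
    return {
        "wilcoxon_p": wres["p"], "wilcoxon_n": wres["n"],
        "mannwhitney_p": float(mres["p_raw"].iloc[0]), "mannwhitney_n": 10,
    }
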