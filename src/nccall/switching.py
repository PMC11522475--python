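"""Paired lineage-switch comparisons and program enrichment statistics.

A lineage switch (e.g. B-ALL relapsing as AML in one patient) is analyzed as
a paired comparison of oncoprotein scores over the shared site universe:
sites called in exactly one phase, ranked by score difference, define the
phase-specific programs. Downstream utilities score expression matrices
against gene programs (per-gene z-scaling, one-sided Wilcoxon signed-rank),
test cofactor signal enrichment over site programs (two-sided Mann-Whitney U,
Bonferroni), and compare log2 fold-change distributions between samples.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "paired_comparison",
    "differential_target_sites",
    "partition_specific_genes",
    "signature_zscore_compare",
    "interval_signal_enrichment",
    "foldchange_group_test",
    "normalize_gene_symbols",
]


def normalize_gene_symbols(genes) -> list[str]:
    """Upper-case, whitespace-stripped gene symbols (no alias resolution)."""
    return [str(g).strip().upper() for g in genes]


def paired_comparison(scores_a: pd.DataFrame, scores_b: pd.DataFrame,
                      sample_a: str = "A", sample_b: str = "B") -> pd.DataFrame:
    """Align two samples' called scores over the shared universe.

    Returns one row per site with onco_score/called for each sample and
    ``delta = score_A - score_B``.
    """
    a = scores_a.set_index("interval_id")
    b = scores_b.set_index("interval_id")
    if set(a.index) != set(b.index):
        raise ValueError("paired_comparison: samples scored on different universes")
    b = b.reindex(a.index)
    out = pd.DataFrame(
        {
            "interval_id": a.index,
            "onco_score_a": a["onco_score"].to_numpy(),
            "onco_score_b": b["onco_score"].to_numpy(),
            "called_a": a["called"].to_numpy(),
            "called_b": b["called"].to_numpy(),
        }
    ).reset_index(drop=True)
    out["delta"] = out["onco_score_a"] - out["onco_score_b"]
    out.attrs["samples"] = (sample_a, sample_b)
    return out


def differential_target_sites(
    pair: pd.DataFrame, top_k: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phase-specific target sites from a paired comparison.

    A-specific sites are called in A but not B, ranked by delta descending
    (B-specific symmetrically by ascending delta). ``top_k`` truncates after
    ranking.
    """
    a_spec = pair[pair["called_a"] & ~pair["called_b"]].sort_values(
        "delta", ascending=False, ignore_index=True
    )
    b_spec = pair[pair["called_b"] & ~pair["called_a"]].sort_values(
        "delta", ascending=True, ignore_index=True
    )
    if len(a_spec) == 0 and len(b_spec) == 0 and not (pair["called_a"] | pair["called_b"]).any():
        warnings.warn("differential_target_sites: no called sites in either sample")
    if top_k is not None:
        a_spec, b_spec = a_spec.head(top_k), b_spec.head(top_k)
    return a_spec, b_spec


def partition_specific_genes(
    specific: set[str] | list[str], other_union: set[str] | list[str]
) -> tuple[set[str], set[str]]:
    """Split phase-specific genes by overlap with all other samples' targets.

    Returns (overlapping, non_overlapping); the non-overlapping half of an
    AML-specific set is what defines a GMP-like program.
    """
    spec = set(normalize_gene_symbols(specific))
    other = set(normalize_gene_symbols(other_union))
    return spec & other, spec - other


def signature_zscore_compare(
    expr: pd.DataFrame,
    program_genes: list[str],
    pairing: list[tuple[str, str]],
    alternative: str = "greater",
    per_sample: bool = False,
) -> dict:
    """Program z-score signature across a paired expression cohort.

    ``expr`` is genes x samples (RPKM or similar); each gene is z-scaled
    across *all* cohort samples (zero-variance genes score 0 with a warning).
    Per-sample program values are mean z over program genes. The test is a
    one-sided Wilcoxon signed-rank on per-gene mean differences between the
    first and second member of each pair (``alternative='greater'`` means the
    first phase is hypothesized higher); ``per_sample=True`` tests per-sample
    program values instead. Exact null enumeration is used at small n.
    """
    genes = [g for g in normalize_gene_symbols(program_genes)
             if g in set(normalize_gene_symbols(expr.index))]
    if not genes:
        raise ValueError("signature_zscore_compare: no program gene present in matrix")
    mat = expr.copy()
    mat.index = normalize_gene_symbols(mat.index)

    mu = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=0)
    if (sd == 0).any():
        warnings.warn(f"{int((sd == 0).sum())} zero-variance genes z-scored as 0")
    z = mat.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)

    program_z = z.loc[genes]
    sample_scores = program_z.mean(axis=0)

    first = [p[0] for p in pairing]
    second = [p[1] for p in pairing]
    if per_sample:
        diffs = (sample_scores[first].to_numpy() - sample_scores[second].to_numpy())
    else:
        diffs = (
            program_z[first].mean(axis=1) - program_z[second].mean(axis=1)
        ).to_numpy()
    method = "exact" if len(diffs) <= 25 else "auto"
    res = stats.wilcoxon(diffs, alternative=alternative, method=method)
    return {
        "per_gene_z": program_z,
        "sample_scores": sample_scores,
        "diffs": diffs,
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "n": len(diffs),
    }


def interval_signal_enrichment(
    signal: pd.Series, sets: dict[str, list[str]], control: list[str]
) -> pd.DataFrame:
    """Mann-Whitney U enrichment of per-interval signal vs an internal control.

    ``signal`` is indexed by interval id (normalized cofactor coverage, e.g.
    CPM base pairs per interval divided by interval length). Each named set is
    compared against the control set by a two-sided Mann-Whitney U test;
    Bonferroni adjustment multiplies by the number of tested sets. The
    control must be disjoint from every tested set.
    """
    ctrl_ids = [i for i in control if i in signal.index]
    rows = []
    tested = 0
    for name, ids in sets.items():
        ids_in = [i for i in ids if i in signal.index]
        if not ids_in:
            warnings.warn(f"interval_signal_enrichment: set {name!r} empty, skipped")
            continue
        if set(ids_in) & set(ctrl_ids):
            raise ValueError(f"set {name!r} overlaps the control set")
        tested += 1
        method = "exact" if max(len(ids_in), len(ctrl_ids)) <= 30 else "auto"
        u, p = stats.mannwhitneyu(
            signal[ids_in], signal[ctrl_ids], alternative="two-sided", method=method
        )
        rows.append({"set": name, "U": float(u), "p_raw": float(p),
                     "n_set": len(ids_in), "n_control": len(ctrl_ids)})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = np.minimum(out["p_raw"] * tested, 1.0)
    return out


def foldchange_group_test(
    fc_a: np.ndarray | pd.Series,
    fc_b: np.ndarray | pd.Series,
    alternative: str = "two-sided",
) -> dict:
    """t-test between two samples' program log2 fold-change distributions.

    ``alternative`` follows scipy ('two-sided', 'greater', 'less'); one-sided
    tests are used when the hypothesis direction is fixed a priori (e.g.
    non-responders vs responders). Gene filtering by adjusted-p inclusion is
    assumed to have happened upstream.
    """
    fc_a, fc_b = np.asarray(fc_a, float), np.asarray(fc_b, float)
    if len(fc_a) < 2 or len(fc_b) < 2:
        raise ValueError("foldchange_group_test: need >=2 genes per group")
    t, p = stats.ttest_ind(fc_a, fc_b, equal_var=False, alternative=alternative)
    return {"t": float(t), "p": float(p), "n_a": len(fc_a), "n_b": len(fc_b)}
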