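"""Cross-sample analysis of oncoprotein scores.

Builds the samples x sites score matrix, decomposes it by PCA, extracts
top-loading site "programs" per component, embeds samples in 2-D with UMAP,
assigns sites to genes, and provides the regression/t-test plumbing used to
compare sample groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .genomic_io import intervals_to_pyranges

__all__ = [
    "assemble_score_matrix",
    "PCAResult",
    "pca_decompose",
    "top_loading_sites",
    "embed_umap",
    "assign_target_genes",
    "groupwise_slope",
    "group_score_test",
]


def _site_sort_key(site_id: str) -> tuple:
    chrom, rest = site_id.split(":", 1)
    start, end = rest.split("-")
    return (chrom, int(start), int(end))


def assemble_score_matrix(
    per_sample_scores: dict[str, pd.DataFrame], universe: list[str] | pd.Index
) -> pd.DataFrame:
    """Samples x sites matrix of oncoprotein scores over a shared universe.

    Rows are sorted by sample id and columns by genomic coordinate, so the
    result is invariant to input ordering. Every sample must score every
    universe site (absent signal still yields a finite score upstream).
    """
    universe = sorted(universe, key=_site_sort_key)
    rows = {}
    for sample_id, scores in per_sample_scores.items():
        s = scores.set_index("interval_id")["onco_score"]
        missing = [u for u in universe if u not in s.index]
        if missing:
            raise ValueError(
                f"sample {sample_id}: {len(missing)} universe sites unscored "
                f"(first: {missing[0]})"
            )
        rows[sample_id] = s.reindex(universe)
    mat = pd.DataFrame(rows).T.loc[sorted(rows)]
    mat.columns.name = "interval_id"
    mat.index.name = "sample_id"
    if mat.isna().any().any():
        raise ValueError("score matrix has missing cells")
    return mat


@dataclass
class PCAResult:
    sample_scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # sites x components
    explained_variance_ratio: np.ndarray


def pca_decompose(matrix: pd.DataFrame, n_components: int) -> PCAResult:
    """PCA of the score matrix on mean-centered, unscaled columns.

    Scores share a common scale across sites, so no variance scaling is
    applied. Component signs follow a fixed convention: the largest-|loading|
    entry of each component is positive.
    """
    if len(matrix) < 2:
        raise ValueError("pca_decompose: need >=2 samples")
    if n_components > min(matrix.shape):
        raise ValueError(
            f"n_components {n_components} > min(n_samples, n_sites) {min(matrix.shape)}"
        )
    X = matrix.to_numpy(dtype=float)
    if np.allclose(X.var(axis=0), 0):
        warnings.warn("pca_decompose: matrix has (near-)zero variance")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    load = pca.components_.T  # sites x components
    flip = np.sign(load[np.abs(load).argmax(axis=0), np.arange(load.shape[1])])
    flip[flip == 0] = 1.0
    load = load * flip
    scores = scores * flip
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        sample_scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(load, index=matrix.columns, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def top_loading_sites(
    pca: PCAResult, component: str | int, fraction: float = 0.05, signed: bool = True
) -> list[str]:
    """Top-fraction sites ranked by loading on one component.

    Ranking is by signed loading (descending) by default, since programs are
    enrichment-directional; ``signed=False`` ranks by |loading|. Ties at the
    rank boundary break toward the lower genomic coordinate. Returns
    ``floor(fraction * n_sites)`` site ids.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    comp = component if isinstance(component, str) else f"PC{component}"
    vals = pca.loadings[comp]
    k = int(np.floor(fraction * len(vals)))
    if k == 0:
        raise ValueError(f"fraction {fraction} of {len(vals)} sites is zero sites")
    key = vals if signed else vals.abs()
    order = sorted(vals.index, key=lambda s: (-key[s], _site_sort_key(s)))
    return order[:k]


def embed_umap(
    pca: PCAResult,
    n_components_used: int = 4,
    seed: int = 42,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> pd.DataFrame:
    """2-D UMAP embedding of samples from the leading principal components.

    Thin wrapper over umap-learn with a fixed seed; hyperparameters are
    recorded in ``result.attrs``. The neighbors parameter is auto-reduced
    (with a warning) when the cohort is smaller than requested.
    """
    import umap  # deferred: numba compilation is slow

    avail = pca.sample_scores.shape[1]
    if n_components_used > avail:
        raise ValueError(f"n_components_used {n_components_used} > available {avail}")
    X = pca.sample_scores.iloc[:, :n_components_used].to_numpy()
    if n_neighbors >= len(X):
        warnings.warn(f"n_neighbors {n_neighbors} >= n_samples {len(X)}; reducing")
        n_neighbors = max(2, len(X) - 1)
    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
    )
    emb = reducer.fit_transform(X)
    out = pd.DataFrame(emb, index=pca.sample_scores.index, columns=["UMAP1", "UMAP2"])
    out.attrs["params"] = {
        "n_components_used": n_components_used,
        "n_neighbors": n_neighbors,
        "min_dist": min_dist,
        "seed": seed,
    }
    return out


def assign_target_genes(
    site_ids: list[str], annotation: pd.DataFrame, promoter_window: int = 2000
) -> tuple[list[str], list[str]]:
    """Map sites to genes by gene-body or promoter-window overlap.

    ``annotation`` columns: gene, chrom, start, end, strand. The promoter
    window extends ``promoter_window`` bp upstream of the TSS (strand-aware).
    Returns (sorted unique gene symbols, unassigned site ids).
    """
    if len(site_ids) == 0:
        return [], []
    sites = pd.DataFrame([_site_sort_key(s) for s in site_ids], columns=["chrom", "start", "end"])
    sites["id"] = list(site_ids)
    plus = annotation["strand"].fillna("+") != "-"
    ext_start = np.where(plus, annotation["start"] - promoter_window, annotation["start"])
    ext_end = np.where(plus, annotation["end"], annotation["end"] + promoter_window)
    genes = pd.DataFrame(
        {"chrom": annotation["chrom"], "start": np.maximum(ext_start, 0), "end": ext_end}
    )
    joined = intervals_to_pyranges(sites, id=sites["id"].to_numpy()).join(
        intervals_to_pyranges(genes, gene=annotation["gene"].to_numpy())
    ).df
    if len(joined) == 0:
        return [], list(site_ids)
    hit_sites = set(joined["id"])
    gene_list = sorted(set(joined["gene"]))
    unassigned = [s for s in site_ids if s not in hit_sites]
    return gene_list, unassigned


def groupwise_slope(points: pd.DataFrame, x: str = "PC1", y: str = "PC2",
                    group: str = "group") -> pd.Series:
    """Ordinary least-squares slope of y on x per sample group.

    Groups with fewer than two points are skipped with a warning.
    """
    slopes = {}
    for name, grp in points.groupby(group):
        if len(grp) < 2:
            warnings.warn(f"groupwise_slope: group {name!r} has <2 samples, skipped")
            continue
        res = stats.linregress(grp[x], grp[y])
        slopes[name] = res.slope
    return pd.Series(slopes, name="slope")


def group_score_test(values: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """Pairwise Welch t-tests between groups with Bonferroni adjustment.

    Returns one row per group pair with t, raw and adjusted (raw x number of
    pairs, capped at 1) two-tailed p-values.
    """
    groups = sorted(labels.unique())
    pairs = list(combinations(groups, 2))
    rows = []
    for a, b in pairs:
        va, vb = values[labels == a], values[labels == b]
        if len(va) < 2 or len(vb) < 2:
            raise ValueError(f"group_score_test: group {a!r} or {b!r} has <2 samples")
        t, p = stats.ttest_ind(va, vb, equal_var=False)
        rows.append({"group_a": a, "group_b": b, "t": t, "p_raw": p,
                     "n_a": len(va), "n_b": len(vb)})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.minimum(out["p_raw"] * len(pairs), 1.0)
    return out
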