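"""Synthetic dual-epitope fragment data with known ground truth.

The generator mirrors the model's multinomial assumption: each track's
fragments distribute multinomially over a planted site layout plus uniform
genomic background. Site classes:

* wild-type sites — bound by full-length protein, so the N- and C-terminal
  antibodies see the same rate (N ~ C);
* oncoprotein sites — bound by the N-terminus-only fusion protein. The
  C-terminal antibody sees only residual wild-type signal there, so by
  default the C-track weight is divided by the effective enrichment fold
  (``fold_mode="c_depletion"``); ``fold_mode="n_inflation"`` instead
  multiplies the N-track weight.
* IgG artifact sites — sticky regions that accumulate signal in *every*
  track, including the IgG control, to exercise control subtraction.

A per-sample oncoprotein level lambda scales the enrichment linearly:
``effective_fold = 1 + lambda * (fold - 1)``, so lambda = 0 is a null sample
and lambda = 1 realizes the configured fold. All randomness flows from one
seed through named substreams, so outputs are fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genomic_io import FragmentSet
from .model import substream

__all__ = ["SimConfig", "SimSample", "simulate_sample", "simulate_cohort",
           "simulate_switch_pair", "effective_fold"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic sample.

    Defaults emulate a CUT&RUN-scale track: 2e5 fragments of ~150 bp (sd 30,
    truncated to [50, 500]), 20% uniform background, 1-kb sites, 8-fold
    oncoprotein enrichment at full oncoprotein level.
    """

    genome: tuple[tuple[str, int], ...] = (("chr1", 5_000_000),)
    n_wt_sites: int = 200
    n_onco_sites: int = 50
    site_length: int = 1000
    onco_fold: float = 8.0
    oncoprotein_level: float = 1.0  # lambda
    depth: int = 200_000
    frag_len_mean: float = 150.0
    frag_len_sd: float = 30.0
    frag_len_range: tuple[int, int] = (50, 500)
    background_fraction: float = 0.2
    igg_artifacts: int = 5
    artifact_weight: float = 10.0  # density multiple at artifact sites
    fold_mode: str = "c_depletion"  # or "n_inflation"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.background_fraction <= 1:
            raise ValueError("background_fraction must lie in [0, 1]")
        if self.onco_fold < 1 or self.oncoprotein_level < 0:
            raise ValueError("onco_fold must be >=1 and oncoprotein_level >=0")
        if self.fold_mode not in ("c_depletion", "n_inflation"):
            raise ValueError(f"unknown fold_mode {self.fold_mode!r}")
        n_sites = self.n_wt_sites + self.n_onco_sites + self.igg_artifacts
        capacity = sum(ln for _, ln in self.genome)
        if n_sites * 2 * self.site_length > capacity:
            raise ValueError("planted sites exceed genome capacity")


@dataclass
class SimSample:
    sample_id: str
    fragments_n: FragmentSet
    fragments_c: FragmentSet
    fragments_igg: FragmentSet
    sites: pd.DataFrame = field(repr=False)  # chrom, start, end, id, class
    truth: pd.DataFrame = field(repr=False)  # site_id, class, effective_fold
    oncoprotein_level: float = 1.0


def effective_fold(fold: float, level: float) -> float:
    """Linear oncoprotein-level link: 1 + level * (fold - 1)."""
    return 1.0 + level * (fold - 1.0)


def _layout_sites(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Evenly spaced non-overlapping sites with shuffled class labels."""
    classes = (
        ["wild_type"] * config.n_wt_sites
        + ["oncoprotein"] * config.n_onco_sites
        + ["igg_artifact"] * config.igg_artifacts
    )
    n = len(classes)
    rng.shuffle(classes)
    rows = []
    remaining = n
    for chrom, length in config.genome:
        take = min(remaining, int(length // (2 * config.site_length)))
        spacing = length // (take + 1) if take else 0
        for i in range(take):
            start = (i + 1) * spacing
            rows.append((chrom, start, start + config.site_length))
        remaining -= take
        if remaining == 0:
            break
    sites = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    sites["id"] = sites["chrom"] + ":" + sites["start"].astype(str) + "-" + sites["end"].astype(str)
    sites["class"] = classes
    return sites


def _track_weights(sites: pd.DataFrame, config: SimConfig, f_eff: float,
                   onco_mask: np.ndarray) -> dict[str, np.ndarray]:
    """Per-site multinomial weights for the N, C and IgG tracks."""
    length = (sites["end"] - sites["start"]).to_numpy(dtype=float)
    art = (sites["class"] == "igg_artifact").to_numpy()
    w_n = length.copy()
    w_c = length.copy()
    if config.fold_mode == "c_depletion":
        w_c[onco_mask] /= f_eff
    else:
        w_n[onco_mask] *= f_eff
    w_n[art] = config.artifact_weight * length[art]
    w_c[art] = config.artifact_weight * length[art]
    w_igg = np.where(art, config.artifact_weight * length, 0.0)
    return {"N": w_n, "C": w_c, "IgG": w_igg}


def _sample_track(
    sites: pd.DataFrame, weights: np.ndarray, config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw one track's fragments: multinomial site allocation + background."""
    total_w = weights.sum()
    bg = config.background_fraction if total_w > 0 else 1.0
    probs = np.concatenate([[bg], (1 - bg) * weights / total_w if total_w > 0 else weights])
    counts = rng.multinomial(config.depth, probs / probs.sum())
    n_bg, site_counts = counts[0], counts[1:]

    lens = rng.normal(config.frag_len_mean, config.frag_len_sd, size=config.depth)
    lens = np.clip(np.rint(lens), *config.frag_len_range).astype(np.int64)

    # on-site fragments: placed uniformly inside their site
    idx = np.repeat(np.arange(len(sites)), site_counts)
    site_start = sites["start"].to_numpy()[idx]
    site_end = sites["end"].to_numpy()[idx]
    flen = np.minimum(lens[: len(idx)], site_end - site_start)
    slack = site_end - site_start - flen
    starts = site_start + np.floor(rng.random(len(idx)) * (slack + 1)).astype(np.int64)
    chroms = sites["chrom"].to_numpy()[idx]

    # background fragments: uniform over the genome
    chrom_names = [c for c, _ in config.genome]
    chrom_lens = np.array([ln for _, ln in config.genome], dtype=float)
    which = rng.choice(len(chrom_names), size=n_bg, p=chrom_lens / chrom_lens.sum())
    bg_lens = np.minimum(lens[len(idx):], chrom_lens[which].astype(np.int64))
    bg_starts = np.floor(
        rng.random(n_bg) * (chrom_lens[which] - bg_lens + 1)
    ).astype(np.int64)

    df = pd.DataFrame(
        {
            "chrom": np.concatenate([chroms, np.array(chrom_names, dtype=object)[which]]),
            "start": np.concatenate([starts, bg_starts]),
            "end": np.concatenate([starts + flen, bg_starts + bg_lens]),
        }
    )
    return df


def simulate_sample(config: SimConfig, sample_id: str = "sim") -> SimSample:
    """Simulate paired N/C tracks plus an IgG control for one sample."""
    layout_rng = substream(config.seed, "sim", "layout")
    sites = _layout_sites(config, layout_rng)
    f_eff = effective_fold(config.onco_fold, config.oncoprotein_level)
    onco = (sites["class"] == "oncoprotein").to_numpy()
    weights = _track_weights(sites, config, f_eff, onco)

    tracks = {}
    for name, w in weights.items():
        rng = substream(config.seed, "sim", sample_id, name)
        frags = _sample_track(sites, w, config, rng)
        antibody = {"N": "MLL-N", "C": "MLL-C", "IgG": "IgG"}[name]
        tracks[name] = FragmentSet(sample_id, antibody, frags, deduplicated=False)

    truth = pd.DataFrame(
        {
            "site_id": sites["id"],
            "class": sites["class"],
            "effective_fold": np.where(onco, f_eff, 1.0),
            "sample": sample_id,
            "lambda": config.oncoprotein_level,
        }
    )
    return SimSample(sample_id, tracks["N"], tracks["C"], tracks["IgG"],
                     sites, truth, config.oncoprotein_level)


def simulate_cohort(
    config: SimConfig,
    group_lambdas: dict[str, list[float]],
    n_onco_per_group: int | None = None,
) -> tuple[dict[str, SimSample], pd.DataFrame, pd.DataFrame]:
    """Simulate a multi-group cohort with disjoint per-group site programs.

    Each group gets its own disjoint block of oncoprotein sites; a sample is
    enriched only at its group's program, at its own oncoprotein level. The
    other groups' program sites behave as wild-type sites for that sample.

    Returns (samples, sample_truth, site_truth): site_truth labels each site
    'wild_type', 'igg_artifact' or 'program:<group>'.
    """
    groups = sorted(group_lambdas)
    per_group = n_onco_per_group if n_onco_per_group is not None else config.n_onco_sites
    layout_cfg = replace(config, n_onco_sites=per_group * len(groups))
    sites = _layout_sites(layout_cfg, substream(config.seed, "sim", "layout"))

    onco_idx = np.flatnonzero((sites["class"] == "oncoprotein").to_numpy())
    prog_rng = substream(config.seed, "sim", "programs")
    prog_rng.shuffle(onco_idx)
    site_class = sites["class"].astype(object).copy()
    program_of: dict[str, np.ndarray] = {}
    for gi, g in enumerate(groups):
        block = onco_idx[gi * per_group: (gi + 1) * per_group]
        program_of[g] = block
        site_class.iloc[block] = f"program:{g}"
    site_truth = sites.assign(**{"class": site_class}).rename(columns={"id": "site_id"})

    samples: dict[str, SimSample] = {}
    sample_rows = []
    for g in groups:
        for si, lam in enumerate(group_lambdas[g]):
            sid = f"{g}_{si + 1}"
            f_eff = effective_fold(config.onco_fold, lam)
            onco_mask = np.zeros(len(sites), dtype=bool)
            onco_mask[program_of[g]] = True
            weights = _track_weights(sites, config, f_eff, onco_mask)
            tracks = {}
            for name, w in weights.items():
                rng = substream(config.seed, "sim", sid, name)
                frags = _sample_track(sites, w, config, rng)
                antibody = {"N": "MLL-N", "C": "MLL-C", "IgG": "IgG"}[name]
                tracks[name] = FragmentSet(sid, antibody, frags, deduplicated=False)
            truth = pd.DataFrame(
                {"site_id": sites["id"], "class": site_class.to_numpy(),
                 "effective_fold": np.where(onco_mask, f_eff, 1.0),
                 "sample": sid, "lambda": lam}
            )
            samples[sid] = SimSample(sid, tracks["N"], tracks["C"], tracks["IgG"],
                                     sites, truth, lam)
            sample_rows.append({"sample_id": sid, "group": g, "lambda": lam})
    return samples, pd.DataFrame(sample_rows), site_truth


def simulate_switch_pair(
    config: SimConfig,
    n_shared: int = 30,
    n_a_only: int = 20,
    n_b_only: int = 20,
    lambda_a: float = 1.0,
    lambda_b: float = 0.5,
    n_expr_pairs: int = 6,
    expr_effect: float = 2.0,
    expr_noise_sd: float = 0.5,
) -> dict:
    """Simulate a patient-matched lineage-switch pair plus an expression matrix.

    Phase A (e.g. B-ALL at diagnosis) carries the shared + A-only programs at
    level ``lambda_a``; phase B (relapse) carries shared + B-only at the
    reduced ``lambda_b``. The paired expression matrix (RPKM-like, genes x
    2*n_expr_pairs samples) shifts one synthetic gene per program site by
    ``expr_effect`` on the log2 scale in the concordant phase, with gaussian
    noise.
    """
    layout_cfg = replace(config, n_onco_sites=n_shared + n_a_only + n_b_only)
    sites = _layout_sites(layout_cfg, substream(config.seed, "sim", "layout"))
    onco_idx = np.flatnonzero((sites["class"] == "oncoprotein").to_numpy())
    rng = substream(config.seed, "sim", "switch-assign")
    rng.shuffle(onco_idx)
    shared = onco_idx[:n_shared]
    a_only = onco_idx[n_shared: n_shared + n_a_only]
    b_only = onco_idx[n_shared + n_a_only:]

    def make(sample_id: str, active: np.ndarray, lam: float) -> SimSample:
        f_eff = effective_fold(config.onco_fold, lam)
        mask = np.zeros(len(sites), dtype=bool)
        mask[active] = True
        weights = _track_weights(sites, config, f_eff, mask)
        tracks = {}
        for name, w in weights.items():
            r = substream(config.seed, "sim", sample_id, name)
            antibody = {"N": "MLL-N", "C": "MLL-C", "IgG": "IgG"}[name]
            tracks[name] = FragmentSet(sample_id, antibody,
                                       _sample_track(sites, w, config, r),
                                       deduplicated=False)
        truth = pd.DataFrame(
            {"site_id": sites["id"], "class": sites["class"],
             "effective_fold": np.where(mask, f_eff, 1.0),
             "sample": sample_id, "lambda": lam}
        )
        return SimSample(sample_id, tracks["N"], tracks["C"], tracks["IgG"],
                         sites, truth, lam)

    sample_a = make("phaseA", np.concatenate([shared, a_only]), lambda_a)
    sample_b = make("phaseB", np.concatenate([shared, b_only]), lambda_b)

    # paired expression cohort: one synthetic gene per program site + controls
    a_genes = [f"GA{i + 1}" for i in range(n_a_only)]
    b_genes = [f"GB{i + 1}" for i in range(n_b_only)]
    ctrl_genes = [f"GC{i + 1}" for i in range(50)]
    genes = a_genes + b_genes + ctrl_genes
    cols = [f"{phase}{p + 1}" for p in range(n_expr_pairs) for phase in ("A", "B")]
    erng = substream(config.seed, "sim", "expression")
    base = erng.normal(5.0, 1.0, size=len(genes))[:, None]
    log2expr = base + erng.normal(0.0, expr_noise_sd, size=(len(genes), len(cols)))
    is_a_phase = np.array([c.startswith("A") for c in cols])
    ga = np.array([g in set(a_genes) for g in genes])
    gb = np.array([g in set(b_genes) for g in genes])
    log2expr[np.ix_(ga, is_a_phase)] += expr_effect
    log2expr[np.ix_(gb, ~is_a_phase)] += expr_effect
    expr = pd.DataFrame(2.0 ** log2expr, index=genes, columns=cols)

    site_gene = pd.DataFrame(
        {"site_id": sites["id"].to_numpy()[np.concatenate([a_only, b_only])],
         "gene": a_genes + b_genes,
         "program": ["A"] * n_a_only + ["B"] * n_b_only}
    )
    return {
        "sample_a": sample_a,
        "sample_b": sample_b,
        "expression": expr,
        "pairing": [(f"A{p + 1}", f"B{p + 1}") for p in range(n_expr_pairs)],
        "a_only_sites": list(sites["id"].to_numpy()[a_only]),
        "b_only_sites": list(sites["id"].to_numpy()[b_only]),
        "shared_sites": list(sites["id"].to_numpy()[shared]),
        "site_gene": site_gene,
        "a_genes": a_genes,
        "b_genes": b_genes,
        "control_genes": ctrl_genes,
    }
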