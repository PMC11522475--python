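"""End-to-end orchestration: manifest-driven per-sample calling and cohort runs.

Stages compose the library modules: fragment I/O -> master-site assembly ->
N/C posterior scoring -> cohort matrix/PCA/programs. Outputs are plain TSV/BED
with a config-hash header comment so reruns are attributable; all randomness
is seeded from the run config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import assembly, cohort, genomic_io
from .model import ModelConfig, average_oncoprotein_score, score_sample

logger = logging.getLogger("nccall")

__all__ = ["RunConfig", "build_master_sites", "run_sample", "run_cohort"]


@dataclass
class RunConfig:
    """All stage parameters; defaults are the published operating point."""

    model: ModelConfig = field(default_factory=ModelConfig)
    fdr_grid: tuple[float, ...] = assembly.DEFAULT_FDR_GRID
    igg_peak_cap: int = assembly.DEFAULT_IGG_PEAK_CAP
    merge_bookended: bool = True
    n_components: int = 4
    top_fraction: float = 0.05
    umap_neighbors: int = 15
    umap_min_dist: float = 0.1
    count_mode: str = "raw"  # raw pooled fragments (see genomic_io docs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        model = ModelConfig(**raw.pop("model", {}))
        return cls(model=model, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_with_header(df: pd.DataFrame, path, config: RunConfig, **to_csv_kw) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# nccall config_hash={config.config_hash()}\n")
        df.to_csv(fh, sep="\t", index=False, **to_csv_kw)


def _load_pooled_track(manifest: pd.DataFrame, sample_id: str, antibody: str) -> genomic_io.FragmentSet:
    rows = manifest[(manifest["sample_id"] == sample_id) & (manifest["antibody"] == antibody)]
    if len(rows) == 0:
        raise ValueError(f"sample {sample_id!r}: no {antibody!r} track in manifest")
    reps = [
        genomic_io.read_fragment_bed(r.path, sample_id, antibody)
        for r in rows.itertuples(index=False)
    ]
    return genomic_io.dedup_and_pool(reps)


def build_master_sites(
    peaksets: list[assembly.PeakSet],
    igg_peaksets: list[assembly.PeakSet] | None = None,
    config: RunConfig = RunConfig(),
) -> pd.DataFrame:
    """Merge N/C peak sets and subtract pooled IgG control peaks."""
    master = assembly.merge_peak_sets(peaksets, merge_bookended=config.merge_bookended)
    logger.info("master list: %d merged intervals", len(master))
    for igg in igg_peaksets or []:
        master = assembly.subtract_control_peaks(master, igg)
        logger.info(
            "IgG subtraction (%s): removed %d intervals",
            igg.sample_id, len(master.attrs["removed_ids"]),
        )
    return master


def run_sample(
    manifest: pd.DataFrame,
    master: pd.DataFrame,
    sample_id: str,
    config: RunConfig = RunConfig(),
    outdir=None,
) -> pd.DataFrame:
    """Score one sample over the master sites and call its target sites."""
    frags_n = _load_pooled_track(manifest, sample_id, "MLL-N")
    frags_c = _load_pooled_track(manifest, sample_id, "MLL-C")
    bp_n = genomic_io.count_bp_overlap(frags_n, master)
    bp_c = genomic_io.count_bp_overlap(frags_c, master)
    counts = pd.DataFrame(
        {"interval_id": master["id"].to_numpy(), "bp_n": bp_n.to_numpy(), "bp_c": bp_c.to_numpy()}
    )
    scores = score_sample(counts, config.model, sample_id)
    logger.info(
        "%s: %d/%d sites called (nc>%g, p<%g, %s p)",
        sample_id, int(scores["called"].sum()), len(scores),
        config.model.nc_threshold, config.model.p_threshold, config.model.p_for_calling,
    )
    if outdir is not None:
        outdir = Path(outdir)
        _write_with_header(scores, outdir / f"{sample_id}.scores.tsv", config)
        called = master[master["id"].isin(scores.loc[scores["called"], "interval_id"])]
        _write_with_header(
            called[["chrom", "start", "end", "id"]],
            outdir / f"{sample_id}.called.bed", config, header=False,
        )
    return scores


def run_cohort(
    manifest: pd.DataFrame,
    master: pd.DataFrame,
    config: RunConfig = RunConfig(),
    outdir=None,
    universe: list[str] | None = None,
) -> dict:
    """Score all manifest samples, build the score matrix and PCA programs.

    ``universe`` defaults to the union of called site ids across samples (the
    combined target-site universe); the matrix itself is complete for every
    sample over that universe.
    """
    sample_ids = sorted(manifest["sample_id"].unique())
    if len(sample_ids) < 2:
        raise ValueError("run_cohort: need >=2 samples")
    per_sample = {
        sid: run_sample(manifest, master, sid, config, outdir) for sid in sample_ids
    }
    if universe is None:
        universe = sorted(
            set().union(*(
                set(s.loc[s["called"], "interval_id"]) for s in per_sample.values()
            ))
        )
    if not universe:
        raise ValueError("run_cohort: no called sites in any sample")
    matrix = cohort.assemble_score_matrix(per_sample, universe)
    n_comp = min(config.n_components, min(matrix.shape))
    pca = cohort.pca_decompose(matrix, n_comp)
    programs = {
        comp: cohort.top_loading_sites(pca, comp, config.top_fraction)
        for comp in pca.loadings.columns
        if int(config.top_fraction * matrix.shape[1]) >= 1
    }
    summary = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "average_onco_score": [
                average_oncoprotein_score(per_sample[s]) for s in sample_ids
            ],
            "n_called": [int(per_sample[s]["called"].sum()) for s in sample_ids],
        }
    )
    if outdir is not None:
        outdir = Path(outdir)
        _write_with_header(matrix.reset_index(), outdir / "score_matrix.tsv", config)
        _write_with_header(
            pca.loadings.reset_index(), outdir / "pca_loadings.tsv", config
        )
        _write_with_header(
            pca.sample_scores.reset_index(), outdir / "pca_scores.tsv", config
        )
        _write_with_header(summary, outdir / "cohort_summary.tsv", config)
        for comp, ids in programs.items():
            pd.Series(ids).to_csv(
                outdir / f"program_{comp}.txt", index=False, header=False
            )
    return {
        "per_sample": per_sample,
        "matrix": matrix,
        "pca": pca,
        "programs": programs,
        "summary": summary,
        "universe": universe,
    }
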