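"""Fragment-level genomic I/O: BED reading, per-replicate deduplication,
replicate pooling, base-pair overlap counting, and normalized coverage tracks.

Coordinates are BED conventions throughout: 0-based, half-open ``[start, end)``.
Strand is ignored; paired-end fragments are assumed to be already collapsed to
single intervals in the input BED files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pyranges as pr

__all__ = [
    "FragmentSet",
    "read_fragment_bed",
    "write_fragment_bed",
    "dedup_and_pool",
    "count_bp_overlap",
    "write_normalized_bedgraph",
    "read_manifest",
    "intervals_to_pyranges",
    "sort_intervals",
]

BED_COLS = ["chrom", "start", "end"]

#: manifest columns expected by the pipeline
MANIFEST_COLS = [
    "sample_id",
    "antibody",
    "replicate",
    "path",
    "plate",
    "lineage",
    "fusion_partner",
]


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Canonical interval sort: (chrom lexicographic, start, end)."""
    return df.sort_values(BED_COLS, kind="mergesort", ignore_index=True)


def _validate_intervals(df: pd.DataFrame, source: str = "<intervals>") -> None:
    if (df["start"] < 0).any():
        i = int(df.index[df["start"] < 0][0])
        raise ValueError(f"{source}: negative start at record {i}")
    bad = df["end"] <= df["start"]
    if bad.any():
        i = int(df.index[bad][0])
        raise ValueError(
            f"{source}: end <= start at record {i} "
            f"({df.loc[i, 'chrom']}:{df.loc[i, 'start']}-{df.loc[i, 'end']})"
        )


@dataclass
class FragmentSet:
    """A set of sequenced fragments for one sample/antibody track.

    ``fragments`` is a DataFrame with columns chrom/start/end in canonical
    sort order. Duplicate fragments (identical chrom, start, end) may be
    present until :func:`dedup_and_pool` is applied.
    """

    sample_id: str
    antibody: str
    fragments: pd.DataFrame = field(repr=False)
    deduplicated: bool = False
    pooled_replicates: int = 1

    def __post_init__(self) -> None:
        self.fragments = sort_intervals(self.fragments[BED_COLS].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.fragments)


def read_fragment_bed(path, sample_id: str, antibody: str) -> FragmentSet:
    """Read a BED3+ fragment file into a :class:`FragmentSet`.

    Extra columns beyond the first three are ignored. Raises ``ValueError``
    naming the offending line on malformed input or invalid coordinates.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if start < 0:
                raise ValueError(f"{path}: line {lineno}: negative start {start}")
            if end <= start:
                raise ValueError(f"{path}: line {lineno}: end {end} <= start {start}")
            rows.append((parts[0], start, end))
    df = pd.DataFrame(rows, columns=BED_COLS)
    return FragmentSet(sample_id=sample_id, antibody=antibody, fragments=df)


def write_fragment_bed(fragset: FragmentSet, path) -> None:
    """Write fragments as BED3 (tab-separated, no header)."""
    fragset.fragments.to_csv(path, sep="\t", header=False, index=False)


def dedup_and_pool(replicates: list[FragmentSet]) -> FragmentSet:
    """Remove duplicate fragments within each replicate, then pool.

    Duplicates are identical (chrom, start, end) triples *within one
    replicate*; identical fragments arising in different replicates are
    retained after pooling. The pooled output is canonically sorted.
    """
    if not replicates:
        raise ValueError("dedup_and_pool: no replicates given")
    sample_ids = {r.sample_id for r in replicates}
    antibodies = {r.antibody for r in replicates}
    if len(sample_ids) != 1 or len(antibodies) != 1:
        raise ValueError(
            f"dedup_and_pool: mixed sample_ids {sample_ids} or antibodies {antibodies}"
        )
    deduped = [
        r.fragments if r.deduplicated else r.fragments.drop_duplicates(BED_COLS)
        for r in replicates
    ]
    pooled = pd.concat(deduped, ignore_index=True) if len(deduped) > 1 else deduped[0]
    return FragmentSet(
        sample_id=replicates[0].sample_id,
        antibody=replicates[0].antibody,
        fragments=pooled.reset_index(drop=True),
        deduplicated=True,
        pooled_replicates=len(replicates),
    )


def intervals_to_pyranges(df: pd.DataFrame, **extra) -> pr.PyRanges:
    out = pd.DataFrame(
        {"Chromosome": df["chrom"].to_numpy(), "Start": df["start"].to_numpy(),
         "End": df["end"].to_numpy()}
    )
    for k, v in extra.items():
        out[k] = v
    return pr.PyRanges(out)


def count_bp_overlap(fragments: FragmentSet, sites: pd.DataFrame) -> pd.Series:
    """Base pairs of fragment signal overlapping each master-site interval.

    ``sites`` must be sorted, non-overlapping intervals with an ``id`` column
    (the master site list). A fragment spanning several sites contributes its
    overlap to each. Returns a Series indexed by site id, in site order.
    """
    _validate_intervals(sites, "master sites")
    s = sites.sort_values(BED_COLS, ignore_index=True)
    same_chrom = s["chrom"].to_numpy()[1:] == s["chrom"].to_numpy()[:-1]
    if np.any(same_chrom & (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1])):
        raise ValueError("count_bp_overlap: master sites overlap; merge them first")

    counts = pd.Series(0, index=pd.Index(s["id"], name="interval_id"), dtype=np.int64)
    if len(fragments) == 0 or len(s) == 0:
        return counts.reindex(sites["id"]).fillna(0).astype(np.int64)

    frag_gr = intervals_to_pyranges(fragments.fragments)
    site_gr = intervals_to_pyranges(s, id=s["id"].to_numpy())
    joined = frag_gr.join(site_gr).df
    if len(joined) > 0:
        ov = (
            np.minimum(joined["End"], joined["End_b"])
            - np.maximum(joined["Start"], joined["Start_b"])
        ).to_numpy()
        bp = pd.Series(ov).groupby(joined["id"].to_numpy()).sum()
        counts.loc[bp.index] = bp.to_numpy()
    return counts.reindex(sites["id"]).fillna(0).astype(np.int64)


def per_base_coverage(fragments: pd.DataFrame) -> pd.DataFrame:
    """Collapse fragments into non-overlapping constant-coverage runs.

    Returns a bedGraph-like DataFrame (chrom, start, end, value) holding the
    per-base fragment pileup, zero-coverage runs omitted, adjacent
    equal-value runs merged.
    """
    records = []
    for chrom, grp in fragments.groupby("chrom", sort=True):
        edges = np.unique(np.concatenate([grp["start"].to_numpy(), grp["end"].to_numpy()]))
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        # coverage over [edges[i], edges[i+1]) via event counting
        delta = np.zeros(len(edges), dtype=np.int64)
        np.add.at(delta, np.searchsorted(edges, starts), 1)
        np.add.at(delta, np.searchsorted(edges, ends), -1)
        cov = np.cumsum(delta)[:-1]
        for i, c in enumerate(cov):
            if c > 0:
                records.append((chrom, int(edges[i]), int(edges[i + 1]), int(c)))
    df = pd.DataFrame(records, columns=["chrom", "start", "end", "value"])
    # merge adjacent equal-value runs
    merged: list[list] = []
    for row in df.itertuples(index=False):
        if merged and merged[-1][0] == row.chrom and merged[-1][2] == row.start and merged[-1][3] == row.value:
            merged[-1][2] = row.end
        else:
            merged.append([row.chrom, row.start, row.end, row.value])
    return pd.DataFrame(merged, columns=["chrom", "start", "end", "value"])


def write_normalized_bedgraph(fragments: FragmentSet, path, scale: str = "cpm") -> pd.DataFrame:
    """Write a coverage bedGraph, optionally counts-per-million normalized.

    ``scale="cpm"`` multiplies per-base coverage by 1e6 / fragment count so
    tracks from different sequencing depths are comparable; ``scale="raw"``
    writes the plain pileup. Returns the track as a DataFrame.
    """
    if scale not in ("cpm", "raw"):
        raise ValueError(f"unknown scale {scale!r}")
    n = len(fragments)
    if n == 0:
        warnings.warn(f"write_normalized_bedgraph: {fragments.sample_id} has zero fragments")
        track = pd.DataFrame(columns=["chrom", "start", "end", "value"])
        track.to_csv(path, sep="\t", header=False, index=False)
        return track
    track = per_base_coverage(fragments.fragments)
    if scale == "cpm":
        track["value"] = track["value"] * (1e6 / n)
    track.to_csv(path, sep="\t", header=False, index=False)
    return track


def read_manifest(path) -> pd.DataFrame:
    """Read the sample manifest TSV and validate required columns."""
    man = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLS if c not in man.columns]
    if missing:
        raise ValueError(f"manifest {path}: missing columns {missing}")
    return man
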