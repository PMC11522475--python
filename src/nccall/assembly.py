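"""Master target-site list assembly.

Per-sample N- and C-terminal peak calls are concatenated and merged into one
shared interval universe; intervals overlapping peaks called on pooled IgG
negative controls are removed outright (non-specific background and
repetitive elements). The IgG peak-calling FDR is relaxed or tightened on a
grid so that no control set contributes an excessive number of peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic_io import BED_COLS, intervals_to_pyranges, sort_intervals

__all__ = [
    "PeakSet",
    "read_peak_bed",
    "merge_peak_sets",
    "subtract_control_peaks",
    "select_control_fdr_threshold",
    "fallback_peak_call",
    "interval_ids",
]

#: default IgG FDR grid, lenient to strict
DEFAULT_FDR_GRID = (0.001, 0.0005, 0.0002, 0.0001)
#: cap on IgG control peaks per plate
DEFAULT_IGG_PEAK_CAP = 2500


@dataclass
class PeakSet:
    """Peak calls for one sample/antibody (e.g. SEACR 'stringent' output)."""

    sample_id: str
    antibody: str
    peaks: pd.DataFrame = field(repr=False)  # chrom, start, end [, score]
    fdr_used: float = 0.01

    def __post_init__(self) -> None:
        cols = BED_COLS + (["score"] if "score" in self.peaks.columns else [])
        self.peaks = sort_intervals(self.peaks[cols].reset_index(drop=True))
        if "score" in self.peaks.columns and (self.peaks["score"] < 0).any():
            raise ValueError("PeakSet: negative peak scores")

    def __len__(self) -> int:
        return len(self.peaks)


def read_peak_bed(path, sample_id: str, antibody: str, fdr_used: float = 0.01) -> PeakSet:
    """Read SEACR-style 6-column output or plain BED3 into a PeakSet."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end", 3: "score"})
    if "score" not in df.columns:
        df["score"] = 0.0
    return PeakSet(sample_id, antibody, df[BED_COLS + ["score"]], fdr_used)


def interval_ids(df: pd.DataFrame) -> pd.Series:
    """Stable interval ids of the form chrom:start-end."""
    return (
        df["chrom"].astype(str)
        + ":"
        + df["start"].astype(str)
        + "-"
        + df["end"].astype(str)
    )


def merge_peak_sets(peaksets: list[PeakSet], merge_bookended: bool = True) -> pd.DataFrame:
    """Concatenate and merge peak sets into a master site list.

    Overlapping intervals always coalesce; bookended (gap-0) intervals merge
    by default. Returns sorted, non-overlapping intervals with stable ids
    (``chrom:start-end``) and a ``provenance`` attribute listing contributing
    peak sets.
    """
    if not peaksets:
        raise ValueError("merge_peak_sets: no peak sets given")
    cat = pd.concat([p.peaks[BED_COLS] for p in peaksets], ignore_index=True)
    if len(cat) == 0:
        raise ValueError("merge_peak_sets: empty union, no sites to analyze")
    slack = 0 if merge_bookended else -1
    merged = intervals_to_pyranges(cat).merge(slack=slack).df
    master = pd.DataFrame(
        {"chrom": merged["Chromosome"].astype(str), "start": merged["Start"],
         "end": merged["End"]}
    )
    master = sort_intervals(master)
    master["id"] = interval_ids(master)
    master.attrs["provenance"] = [f"{p.sample_id}/{p.antibody}" for p in peaksets]
    return master


def subtract_control_peaks(master: pd.DataFrame, igg: PeakSet) -> pd.DataFrame:
    """Drop every master interval overlapping an IgG control peak by >=1 bp.

    Removal is whole-interval (no truncation). Removed ids are recorded in
    ``result.attrs["removed_ids"]``.
    """
    if len(igg) == 0 or len(master) == 0:
        out = master.copy()
        out.attrs["removed_ids"] = []
        return out
    mgr = intervals_to_pyranges(master, id=master["id"].to_numpy())
    kept = mgr.overlap(intervals_to_pyranges(igg.peaks), invert=True).df
    kept_ids = set(kept["id"]) if len(kept) else set()
    out = master[master["id"].isin(kept_ids)].reset_index(drop=True)
    out.attrs["removed_ids"] = sorted(set(master["id"]) - kept_ids)
    return out


def select_control_fdr_threshold(
    peak_counts: dict[float, int],
    grid: list[float] | tuple[float, ...] = DEFAULT_FDR_GRID,
    cap: int = DEFAULT_IGG_PEAK_CAP,
) -> float:
    """Most lenient FDR on the grid calling at most ``cap`` IgG peaks.

    ``peak_counts`` maps FDR -> number of control peaks called at that FDR.
    Falls back to the strictest grid value (with a warning) if every grid
    point exceeds the cap.
    """
    if not grid:
        raise ValueError("select_control_fdr_threshold: empty FDR grid")
    if cap <= 0:
        raise ValueError("select_control_fdr_threshold: cap must be positive")
    ordered = sorted(grid, reverse=True)  # lenient (large FDR) first
    for fdr in ordered:
        if peak_counts.get(fdr, np.inf) <= cap:
            return fdr
    warnings.warn(
        f"no FDR on grid keeps control peaks <= {cap}; using strictest {ordered[-1]}"
    )
    return ordered[-1]


def fallback_peak_call(
    track: pd.DataFrame,
    quantile: float = 0.95,
    sample_id: str = "<track>",
    antibody: str = "fallback",
) -> PeakSet:
    """Simple quantile-threshold peak caller over a binned coverage track.

    ``track`` is a bedGraph-like frame (chrom, start, end, value) of
    contiguous equal-width or run-length bins. Bins whose value exceeds the
    given coverage quantile are merged into peaks when contiguous. This is
    plumbing for synthetic data, not a re-implementation of a published
    caller.
    """
    if len(track) == 0:
        warnings.warn("fallback_peak_call: empty track, zero peaks")
        return PeakSet(sample_id, antibody, pd.DataFrame(columns=BED_COLS + ["score"]))
    vals = track["value"].to_numpy(dtype=float)
    thresh = np.quantile(vals, quantile)
    above = track[vals > thresh]
    if len(above) == 0:
        warnings.warn("fallback_peak_call: flat or degenerate track, zero peaks")
        return PeakSet(sample_id, antibody, pd.DataFrame(columns=BED_COLS + ["score"]))
    merged = intervals_to_pyranges(above).merge(slack=0).df
    peaks = pd.DataFrame(
        {"chrom": merged["Chromosome"].astype(str), "start": merged["Start"],
         "end": merged["End"], "score": 0.0}
    )
    # score each peak with its max bin value
    gr = intervals_to_pyranges(above, value=above["value"].to_numpy())
    joined = intervals_to_pyranges(peaks).join(gr).df
    if len(joined):
        key = joined["Chromosome"].astype(str) + ":" + joined["Start"].astype(str)
        mx = joined.groupby(key.to_numpy())["value"].max()
        pk = peaks["chrom"] + ":" + peaks["start"].astype(str)
        peaks["score"] = pk.map(mx).fillna(0.0).to_numpy()
    return PeakSet(sample_id, antibody, peaks)
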