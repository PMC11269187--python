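"""Single-base TSS calling from 5'-end read-count tables.

Capped-small-RNA sequencing maps the 5' nucleotide of each read to a
putative TSS.  This module applies the two confidence filters used for such
data — a minimum normalized read count (default 7 reads per 10^7 aligned
reads, pooled across all compared samples) and an input-dominance filter
discarding positions where the small-RNA input library has higher
normalized density than the capped library — and groups the surviving
single-base TSSs into transcription start regions (TSRs).

Tracks are DataFrames with columns (chrom, pos, strand, count); library
size defaults to the track's total count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("tssgrammar")

TRACK_COLUMNS = ["chrom", "pos", "strand", "count"]
KEY = ["chrom", "pos", "strand"]


@dataclass
class FivePrimeTrack:
    """Per-(chrom, pos, strand) 5'-end read counts for one sample."""

    counts: pd.DataFrame
    library_size: float | None = None

    def __post_init__(self) -> None:
        if not set(TRACK_COLUMNS) <= set(self.counts.columns):
            raise ValueError(f"track needs columns {TRACK_COLUMNS}")
        if (self.counts["count"] < 0).any():
            raise ValueError("negative counts")
        if self.library_size is None:
            self.library_size = float(self.counts["count"].sum())
        if self.library_size <= 0:
            raise ValueError("library size must be > 0")


@dataclass
class TSR:
    """A transcription start region: closely spaced same-strand TSSs."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # inclusive
    strand: str
    members: list[int] = field(default_factory=list)
    total_count: float = 0.0


def normalize_counts(track: FivePrimeTrack, scale: float = 1e7) -> pd.DataFrame:
    """Counts rescaled to reads per ``scale`` total aligned reads."""
    out = track.counts.copy()
    out["norm"] = out["count"] * scale / track.library_size
    return out


def call_confident_tss(
    tracks: list[FivePrimeTrack],
    min_norm: float = 7.0,
    scale: float = 1e7,
    mode: str = "pooled",
) -> pd.DataFrame:
    """Retain positions with sufficient normalized 5'-end coverage.

    pooled mode (default): a position is kept iff the sum of its per-sample
    normalized counts (reads per 10^7) across all compared samples is at
    least ``min_norm``.  per_sample mode keeps a position only when every
    sample individually reaches ``min_norm``.

    Returns a frame (chrom, pos, strand, norm) of surviving TSS positions.
    """
    if not tracks:
        raise ValueError("need at least one track")
    if mode not in {"pooled", "per_sample"}:
        raise ValueError(f"unknown mode {mode!r}")
    normed = [normalize_counts(t, scale) for t in tracks]
    merged = pd.concat(normed)[KEY + ["norm"]]
    if mode == "pooled":
        agg = merged.groupby(KEY, sort=True)["norm"].sum().reset_index()
        keep = agg["norm"] >= min_norm
    else:
        g = merged.groupby(KEY, sort=True)["norm"]
        agg = g.min().reset_index()
        n_samples = g.size().reset_index(drop=True)
        keep = (agg["norm"] >= min_norm) & (n_samples == len(tracks))
    return agg[keep].reset_index(drop=True)


def filter_input_dominated(
    tss: pd.DataFrame,
    cs_track: FivePrimeTrack,
    input_track: FivePrimeTrack | None,
    scale: float = 1e7,
) -> pd.DataFrame:
    """Drop TSS positions whose normalized input density exceeds the capped
    library's (likely false positives: abundant non-capped RNA species).

    Ties are kept: only strictly higher input density discards a position.
    Without an input track the TSS set passes through with a warning.
    """
    if input_track is None:
        logger.warning("no input track supplied: input-dominance filter "
                       "skipped entirely")
        return tss.copy()
    cs = normalize_counts(cs_track, scale).set_index(KEY)["norm"]
    inp = normalize_counts(input_track, scale).set_index(KEY)["norm"]
    idx = pd.MultiIndex.from_frame(tss[KEY])
    cs_v = cs.reindex(idx).fillna(0.0).to_numpy()
    in_v = inp.reindex(idx).fillna(0.0).to_numpy()
    keep = ~(in_v > cs_v)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("input-dominance filter dropped %d positions", dropped)
    return tss[keep].reset_index(drop=True)


def cluster_tsr(tss: pd.DataFrame, max_gap: int = 150) -> list[TSR]:
    """Greedy single-linkage grouping of same-strand TSSs within ``max_gap`` bp.

    Deterministic: positions are processed in sorted (chrom, strand, pos)
    order; consecutive positions at most ``max_gap`` apart join one TSR.
    """
    tsrs: list[TSR] = []
    value_col = "norm" if "norm" in tss.columns else (
        "count" if "count" in tss.columns else None)
    for (chrom, strand), grp in tss.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values("pos")
        cur: TSR | None = None
        for row in grp.itertuples(index=False):
            pos = int(row.pos)
            val = float(getattr(row, value_col)) if value_col else 0.0
            if cur is not None and pos - cur.end <= max_gap:
                cur.end = pos
                cur.members.append(pos)
                cur.total_count += val
            else:
                if cur is not None:
                    tsrs.append(cur)
                cur = TSR(chrom, pos, pos, strand, [pos], val)
        if cur is not None:
            tsrs.append(cur)
    return tsrs


def tsrs_to_bed6(tsrs: list[TSR]) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [t.chrom for t in tsrs],
        "start": [t.start for t in tsrs],
        "end": [t.end + 1 for t in tsrs],  # BED half-open
        "name": [f"TSR_{i}" for i in range(len(tsrs))],
        "score": [t.total_count for t in tsrs],
        "strand": [t.strand for t in tsrs],
    })


# ---------------------------------------------------------------------------
# I/O: per-sample TSV or strand-split bedGraph


def read_track_tsv(path, library_size: float | None = None) -> FivePrimeTrack:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return FivePrimeTrack(df[TRACK_COLUMNS], library_size)


def write_track_tsv(track: FivePrimeTrack, path) -> None:
    track.counts[TRACK_COLUMNS].to_csv(path, sep="\t", index=False)


def read_bedgraph_pair(plus_path, minus_path,
                       library_size: float | None = None) -> FivePrimeTrack:
    """Read strand-split bedGraph files of single-base 5'-end counts."""
    frames = []
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "count"],
                         comment="t", dtype={"chrom": str})
        rows = []
        for r in df.itertuples(index=False):
            for pos in range(int(r.start), int(r.end)):
                rows.append((r.chrom, pos, strand, abs(float(r.count))))
        frames.append(pd.DataFrame(rows, columns=TRACK_COLUMNS))
    return FivePrimeTrack(pd.concat(frames, ignore_index=True), library_size)


def write_bedgraph_pair(track: FivePrimeTrack, plus_path, minus_path,
                        normalized: bool = True, scale: float = 1e7) -> None:
    df = normalize_counts(track, scale) if normalized else track.counts.assign(
        norm=track.counts["count"])
    for path, strand, sign in ((plus_path, "+", 1), (minus_path, "-", -1)):
        sub = df[df["strand"] == strand].sort_values(["chrom", "pos"])
        with open(path, "w") as fh:
            for r in sub.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{sign * r.norm:g}\n")
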