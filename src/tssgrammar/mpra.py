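"""TSS-MPRA quantification: start-site matrices to activity, sweeps and shifts.

A TSS-MPRA reads out transcription initiation at base resolution for a
library of designed reporter inserts.  Quantification follows a fixed
recipe: per-insert start-site counts are scaled by min(10000/plasmid, 100)
to correct for plasmid representation (inserts with < 50 plasmid DNA
alignments are unusable), a pseudocount of 1 is added and values are log2
transformed, and barcode/technical replicates are merged by averaging.
Downstream summaries include binding-site sweep profiles (effect of a motif
as a function of its distance to the TSS), insertion effects in a +/-7 bp
window around the designated TSS, and weighted-mean TSS shifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("tssgrammar")

MIN_PLASMID = 50  # inserts with fewer total DNA alignments are unusable


@dataclass
class InsertMatrix:
    """Start-site counts for one MPRA insert (one barcode of one design)."""

    insert_id: str
    promoter: str
    motif: str
    planted_pos: int | None
    barcode: str
    replicate: str
    plasmid_dna_count: int
    start_counts: np.ndarray

    def __post_init__(self) -> None:
        self.start_counts = np.asarray(self.start_counts)
        if (self.start_counts < 0).any():
            raise ValueError(f"insert {self.insert_id}: negative counts")
        if self.plasmid_dna_count < 0:
            raise ValueError(f"insert {self.insert_id}: negative plasmid count")

    @property
    def usable(self) -> bool:
        return self.plasmid_dna_count >= MIN_PLASMID


@dataclass
class SweepProfile:
    """Mean log2 activity change per motif-to-TSS distance."""

    distances: np.ndarray
    mean_delta: np.ndarray
    smoothed: np.ndarray  # LOESS(span 0.1) visual track, never used for stats
    n_inserts: int = 0


def scaling_factor(plasmid: int) -> float:
    """min(10000/plasmid, 100): plasmid-representation correction, capped."""
    return min(10000.0 / plasmid, 100.0)


def scale_insert(matrix: InsertMatrix) -> np.ndarray:
    """Scaled counts: counts * min(10000/plasmid, 100) (no log)."""
    if not matrix.usable:
        raise ValueError(
            f"insert {matrix.insert_id}: plasmid count "
            f"{matrix.plasmid_dna_count} < {MIN_PLASMID}; insert is unusable")
    return matrix.start_counts * scaling_factor(matrix.plasmid_dna_count)


def scale_insert_log2(matrix: InsertMatrix) -> np.ndarray:
    """log2(scaled counts + 1) per position."""
    return np.log2(scale_insert(matrix) + 1.0)


def merge_replicates(vectors: list[np.ndarray]) -> np.ndarray:
    """Average per-position signal across barcode/technical replicates."""
    if not vectors:
        raise ValueError("nothing to merge")
    lengths = {len(v) for v in vectors}
    if len(lengths) != 1:
        raise ValueError("inserts with mismatched lengths")
    return np.mean(np.stack(vectors), axis=0)


def merged_log2_by_insert(inserts: list[InsertMatrix]
                          ) -> tuple[dict[str, np.ndarray], list[str]]:
    """Scaled log2 vectors averaged over an insert's barcodes/replicates.

    Unusable inserts (plasmid < 50) are excluded and listed.
    """
    groups: dict[str, list[np.ndarray]] = {}
    excluded: list[str] = []
    for m in inserts:
        if not m.usable:
            excluded.append(m.insert_id)
            continue
        groups.setdefault(m.insert_id, []).append(scale_insert_log2(m))
    if excluded:
        logger.info("excluded %d unusable inserts (plasmid < %d)",
                    len(excluded), MIN_PLASMID)
    return {k: merge_replicates(v) for k, v in groups.items()}, excluded


# ---------------------------------------------------------------------------
# LOESS (tricube weights, degree 2) - visualization smoothing only


def loess_smooth(x: np.ndarray, y: np.ndarray, span: float = 0.1,
                 degree: int = 2) -> np.ndarray:
    """Local polynomial regression with tricube weights.

    ``span`` is the fraction of points in each local neighbourhood.  Used
    only for visual tracks; statistics are computed on unsmoothed values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    q = max(degree + 1, int(np.ceil(span * n)))
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argpartition(d, q - 1)[:q]
        dmax = d[idx].max()
        w = (1 - (d[idx] / max(dmax, 1e-12)) ** 3) ** 3
        w = np.maximum(w, 1e-9)
        coeffs = np.polyfit(x[idx] - x[i], y[idx], deg=degree, w=np.sqrt(w))
        out[i] = coeffs[-1]
    return out


# ---------------------------------------------------------------------------
# Sweep analysis


def sweep_delta(
    inserts: list[InsertMatrix],
    span: float = 0.1,
) -> tuple[pd.DataFrame, SweepProfile]:
    """Per-insert activity deltas and the motif-distance sweep profile.

    Reference coverage is the position-wise mean of the merged log2 signal
    across all inserts of the sweep; each insert's delta track is its signal
    minus the reference.  For the profile every position is re-indexed by
    its distance to the insert's planted motif position and deltas are
    averaged per distance.  LOESS (span 0.1) smoothing is applied to the
    visual profile only.
    """
    merged, _ = merged_log2_by_insert(inserts)
    if len(merged) < 5:
        raise ValueError("need at least 5 usable inserts in a sweep")
    meta = {m.insert_id: m for m in inserts}
    ids = sorted(merged)
    mat = np.stack([merged[i] for i in ids])
    reference = mat.mean(axis=0)
    deltas = mat - reference

    L = mat.shape[1]
    rows = []
    acc: dict[int, list[float]] = {}
    for row_i, iid in enumerate(ids):
        planted = meta[iid].planted_pos
        if planted is None:
            continue
        for pos in range(L):
            acc.setdefault(pos - planted, []).append(deltas[row_i, pos])
        rows.append(iid)
    dists = np.array(sorted(acc))
    mean_delta = np.array([np.mean(acc[d]) for d in dists])
    smoothed = loess_smooth(dists.astype(float), mean_delta, span=span) \
        if len(dists) > 3 else mean_delta.copy()
    delta_table = pd.DataFrame(deltas, index=ids,
                               columns=np.arange(L)).rename_axis("insert_id")
    profile = SweepProfile(distances=dists, mean_delta=mean_delta,
                           smoothed=smoothed, n_inserts=len(rows))
    return delta_table, profile


# ---------------------------------------------------------------------------
# Insertion effects and TSS shifts


def insertion_effect(
    insert: list[InsertMatrix] | np.ndarray,
    control: list[InsertMatrix] | np.ndarray,
    tss_pos: int,
    tss_window: int = 7,
) -> float:
    """log2 ratio of scaled start-site signal near the designated TSS.

    The window is +/-``tss_window`` bp around ``tss_pos``, inclusive at both
    ends (15 positions by default).  Barcodes are averaged (on the scaled,
    unlogged counts) before the ratio.  A zero control window makes the
    effect undefined (NaN, with a warning).
    """
    def _merged_scaled(x) -> np.ndarray:
        if isinstance(x, np.ndarray):
            return x
        vecs = [scale_insert(m) for m in x if m.usable]
        if not vecs:
            raise ValueError("no usable inserts")
        return merge_replicates(vecs)

    ins = _merged_scaled(insert)
    ctl = _merged_scaled(control)
    lo, hi = max(0, tss_pos - tss_window), min(len(ins), tss_pos + tss_window + 1)
    num = ins[lo:hi].sum()
    den = ctl[lo:hi].sum()
    if den == 0:
        logger.warning("zero control signal in TSS window: effect undefined")
        return float("nan")
    if num == 0:
        return float("-inf")
    return float(np.log2(num / den))


def tss_shift(
    mutant: np.ndarray | list[InsertMatrix],
    control: np.ndarray | list[InsertMatrix],
) -> float:
    """Weighted-mean TSS position of the mutant minus the control's.

    Weights are scaled start-site counts; zero total signal in either insert
    makes the shift undefined (NaN, flagged by a warning).
    """
    def _scaled(x) -> np.ndarray:
        if isinstance(x, np.ndarray):
            return x
        return merge_replicates([scale_insert(m) for m in x if m.usable])

    m, c = _scaled(mutant), _scaled(control)

    def _wmean(v: np.ndarray) -> float:
        tot = v.sum()
        if tot <= 0:
            return float("nan")
        return float((np.arange(len(v)) * v).sum() / tot)

    wm, wc = _wmean(m), _wmean(c)
    if np.isnan(wm) or np.isnan(wc):
        logger.warning("zero total signal: TSS shift undefined")
        return float("nan")
    return wm - wc


# ---------------------------------------------------------------------------
# Mutation-position classification


def classify_mutation_positions(
    sites: pd.DataFrame,
    enrichment_map,
    alpha: float = 0.01,
    min_promoters: int = 20,
) -> pd.DataFrame:
    """Label mutated binding sites by the genomic positional-enrichment sign.

    ``sites`` needs columns (motif, promoter, rel_pos).  A site is
    'enriched-position' when a significant (P_adj < alpha) positive cell of
    the enrichment map covers its position, 'depleted-position' for a
    negative cell, 'neutral' when no significant cell covers it.  Motifs
    represented by fewer than ``min_promoters`` distinct promoters are
    excluded from the output summary (flagged in the 'included' column).
    """
    emap = enrichment_map.table
    out_rows = []
    for r in sites.itertuples(index=False):
        cells = emap[(emap["motif"] == r.motif)
                     & (emap["window_start"] <= r.rel_pos)
                     & (emap["window_end"] >= r.rel_pos)
                     & (emap["p_adj"] < alpha)]
        if cells.empty:
            label = "neutral"
        elif (cells["signed_logP"] > 0).any() and not \
                (cells["signed_logP"] < 0).any():
            label = "enriched-position"
        elif (cells["signed_logP"] < 0).any() and not \
                (cells["signed_logP"] > 0).any():
            label = "depleted-position"
        else:  # conflicting overlapping cells: take the strongest
            top = cells.loc[cells["signed_logP"].abs().idxmax()]
            label = ("enriched-position" if top["signed_logP"] > 0
                     else "depleted-position")
        out_rows.append((r.motif, r.promoter, r.rel_pos, label))
    out = pd.DataFrame(out_rows, columns=["motif", "promoter", "rel_pos",
                                          "label"])
    n_prom = out.groupby("motif")["promoter"].transform("nunique")
    out["included"] = n_prom >= min_promoters
    return out


# ---------------------------------------------------------------------------
# I/O


def read_insert_tables(design_path, counts_path, plasmid_path
                       ) -> list[InsertMatrix]:
    """Assemble InsertMatrix objects from the three TSV inputs.

    design: oligo_id, insert_id, promoter, motif, planted_pos, barcode,
    replicate (oligo_id is unique per barcode x replicate; barcodes of one
    design share insert_id and are merged downstream);
    counts: oligo_id x position matrix (first column oligo_id);
    plasmid: oligo_id, plasmid_dna_count.
    """
    design = pd.read_csv(design_path, sep="\t")
    counts = pd.read_csv(counts_path, sep="\t", dtype={"oligo_id": str}
                         ).set_index("oligo_id")
    plasmid = pd.read_csv(plasmid_path, sep="\t", dtype={"oligo_id": str}
                          ).set_index("oligo_id")
    inserts = []
    for r in design.itertuples(index=False):
        planted = None if pd.isna(r.planted_pos) else int(r.planted_pos)
        oid = str(r.oligo_id)
        inserts.append(InsertMatrix(
            insert_id=str(r.insert_id), promoter=str(r.promoter),
            motif=str(r.motif), planted_pos=planted, barcode=str(r.barcode),
            replicate=str(r.replicate),
            plasmid_dna_count=int(plasmid.loc[oid, "plasmid_dna_count"]),
            start_counts=counts.loc[oid].to_numpy(dtype=float),
        ))
    return inserts
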