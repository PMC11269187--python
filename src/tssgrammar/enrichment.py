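"""PWM scanning and TSS-anchored windowed enrichment/depletion maps.

A motif's positional preference is summarized as a signed log10 adjusted
P-value per (motif, window) cell: positive for enrichment in the targets
relative to a matched background, negative for depletion.  Windows are
evaluated on a start/width/step grid over anchor-relative coordinates and
tested with one-sided Fisher exact tests (hypergeometric tail in the
direction of the observed effect), Benjamini-Hochberg corrected jointly
across every cell of one invocation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .seqmodel import PWM, AnchoredWindow, MotifHit
from . import background as bg

P_FLOOR = 1e-300  # numerical floor before taking logs

HIT_COLUMNS = ["motif", "window_id", "seq_index", "rel_pos", "strand_of_hit",
               "score"]


# ---------------------------------------------------------------------------
# PWM scanning


def _offset_scores(mat: np.ndarray, pwm: PWM) -> np.ndarray:
    """(n, L - Lm + 1) log2-odds at every offset; windows spanning an N
    score -inf (no hit can span an N)."""
    lo = np.concatenate([pwm.log_odds, np.full((len(pwm), 1), -np.inf)], axis=1)
    n, L = mat.shape
    n_off = L - len(pwm) + 1
    if n_off <= 0:
        return np.zeros((n, 0))
    scores = np.zeros((n, n_off))
    for j in range(len(pwm)):
        scores += lo[j, mat[:, j : j + n_off]]
    return scores


def hit_centers(
    mat: np.ndarray, pwm: PWM, strand_mode: str = "both", up: int = 0
) -> pd.DataFrame:
    """Above-threshold hits on an encoded matrix.

    Returns a frame with seq_index, rel_pos (motif center, anchor-relative
    when ``up`` is the upstream extent), strand_of_hit and score.
    """
    if strand_mode not in {"sense", "antisense", "both", "separate"}:
        raise ValueError(f"invalid strand_mode {strand_mode!r}")
    parts = []
    modes = {"sense": ["sense"], "antisense": ["antisense"]}.get(
        strand_mode, ["sense", "antisense"])
    for label in modes:
        p = pwm if label == "sense" else pwm.reverse_complement()
        scores = _offset_scores(mat, p)
        si, off = np.where(scores >= pwm.detection_threshold)
        # Center of the occupied span in window coordinates (rounded toward
        # the window's 5' end) for both strands, so sense and antisense
        # placements of the same site coincide.
        c = p.center_index
        parts.append(pd.DataFrame({
            "seq_index": si,
            "rel_pos": off + c - up,
            "strand_of_hit": label,
            "score": scores[si, off],
        }))
    out = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["seq_index", "rel_pos", "strand_of_hit", "score"])
    return out.sort_values(["seq_index", "rel_pos"], kind="stable",
                           ignore_index=True)


def scan_pwm(
    windows: list[AnchoredWindow] | np.ndarray,
    pwm: PWM,
    strand_mode: str = "both",
    up: int | None = None,
) -> list[MotifHit]:
    """Scan windows for PWM matches with log2-odds >= detection threshold.

    Hit positions follow the center convention (center column, rounded
    toward 5' for even motif lengths).  In 'separate' mode sense and
    antisense hits carry their strand label and are never merged; 'both'
    reports hits from either strand.
    """
    if isinstance(windows, np.ndarray):
        mat = windows
        ids = [str(i) for i in range(len(mat))]
        up = 0 if up is None else up
    else:
        mat = bg._as_matrix(windows)
        ids = [w.window_id for w in windows]
        ups = {w.up for w in windows}
        if len(ups) != 1:
            raise ValueError("windows have mixed upstream extents")
        up = ups.pop()
    table = hit_centers(mat, pwm, strand_mode, up=up)
    return [
        MotifHit(pwm.name, ids[r.seq_index], int(r.rel_pos), r.strand_of_hit,
                 float(r.score))
        for r in table.itertuples(index=False)
    ]


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    if not hits:
        return pd.DataFrame(columns=HIT_COLUMNS[:2] + HIT_COLUMNS[3:])
    return pd.DataFrame(
        {
            "motif": [h.motif for h in hits],
            "window_id": [h.window_id for h in hits],
            "rel_pos": [h.rel_pos for h in hits],
            "strand_of_hit": [h.strand_of_hit for h in hits],
            "score": [h.score for h in hits],
        }
    )


# ---------------------------------------------------------------------------
# Window grid


def grid_windows(rng: tuple[int, int], width: int, step: int
                 ) -> list[tuple[int, int]]:
    """Evaluation windows [start, end] (inclusive): starts every ``step`` bp
    from rng[0] through rng[1], windows clipped at the range end.  The
    -150..+100 / width 30 / step 10 grid yields 26 windows."""
    if width < 1 or step < 1:
        raise ValueError("width and step must be >= 1")
    lo, hi = rng
    return [(s, min(s + width - 1, hi)) for s in range(lo, hi + 1, step)]


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR adjustment (monotone in ranks, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Windowed enrichment


@dataclass
class EnrichmentMap:
    """Motif x window grid of hit counts and signed log10 adjusted P-values.

    ``table`` is long format with one row per (motif, strand, window) cell;
    signed_logP is -log10(P_adj) for enrichment, +log10(P_adj) for depletion
    (i.e. positive = enriched, negative = depleted).
    """

    table: pd.DataFrame
    grid: list[tuple[int, int]]
    n_target: int
    n_background: int

    def matrix(self, value: str = "signed_logP") -> pd.DataFrame:
        """Pivot to (motif, strand) rows x window-start columns."""
        return self.table.pivot_table(
            index=["motif", "strand"], columns="window_start", values=value
        )

    def global_max_window(self) -> tuple[int, int]:
        """Window (start, end) holding the largest signed_logP."""
        row = self.table.loc[self.table["signed_logP"].idxmax()]
        return int(row["window_start"]), int(row["window_end"])

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_adj"] < alpha]


def _directional_fisher(a: np.ndarray, b: np.ndarray, n1: int, n2: int
                        ) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Fisher exact P in the direction of the observed effect.

    a, b: per-cell counts of target / background sequences with a hit.
    Returns (p, direction) with direction +1 when the target proportion is
    at least the background proportion, else -1.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    M = n1 + n2
    K = a + b
    direction = np.where(a * n2 >= b * n1, 1, -1)
    p_enr = stats.hypergeom.sf(a - 1, M, K, n1)
    p_dep = stats.hypergeom.cdf(a, M, K, n1)
    p = np.where(direction > 0, p_enr, p_dep)
    return np.clip(p, 0.0, 1.0), direction


def windowed_enrichment(
    target_hits: pd.DataFrame | list[MotifHit],
    background_hits: pd.DataFrame | list[MotifHit],
    n_target: int,
    n_background: int,
    rng: tuple[int, int] = (-150, 100),
    width: int = 30,
    step: int = 10,
) -> EnrichmentMap:
    """Fisher-exact enrichment/depletion over a window grid.

    Counting is sequence-level: a sequence contributes once per window if it
    has >= 1 hit center inside the window (occurrence counts would violate
    the independence assumption of the 2x2 table).  BH correction is applied
    jointly across all (motif, strand, window) cells of this invocation.
    """
    if n_target <= 0 or n_background <= 0:
        raise ValueError("totals must be > 0")
    if isinstance(target_hits, list):
        target_hits = hits_to_frame(target_hits)
    if isinstance(background_hits, list):
        background_hits = hits_to_frame(background_hits)
    grid = grid_windows(rng, width, step)

    keys = sorted(
        set(map(tuple, target_hits[["motif", "strand_of_hit"]].drop_duplicates()
                .itertuples(index=False)))
        | set(map(tuple, background_hits[["motif", "strand_of_hit"]]
                  .drop_duplicates().itertuples(index=False)))
    )
    if not keys:
        keys = [("", "both")]

    rows = []
    for motif, strand in keys:
        th = target_hits[(target_hits["motif"] == motif)
                         & (target_hits["strand_of_hit"] == strand)]
        bh = background_hits[(background_hits["motif"] == motif)
                             & (background_hits["strand_of_hit"] == strand)]
        for (ws, we) in grid:
            a = th.loc[(th["rel_pos"] >= ws) & (th["rel_pos"] <= we),
                       "window_id"].nunique()
            b = bh.loc[(bh["rel_pos"] >= ws) & (bh["rel_pos"] <= we),
                       "window_id"].nunique()
            rows.append((motif, strand, ws, we, a, b))
    table = pd.DataFrame(
        rows, columns=["motif", "strand", "window_start", "window_end",
                       "target_count", "background_count"]
    )
    return _finalize_map(table, grid, n_target, n_background)


def _finalize_map(table: pd.DataFrame, grid, n_target: int, n_background: int
                  ) -> EnrichmentMap:
    p, direction = _directional_fisher(
        table["target_count"].to_numpy(), table["background_count"].to_numpy(),
        n_target, n_background)
    table = table.copy()
    table["p"] = p
    table["p_adj"] = benjamini_hochberg(p)
    table["signed_logP"] = direction * -np.log10(
        np.maximum(table["p_adj"].to_numpy(), P_FLOOR))
    table["empty"] = (table["target_count"] == 0) & (table["background_count"] == 0)
    return EnrichmentMap(table=table, grid=list(grid), n_target=n_target,
                         n_background=n_background)


def motif_density_histogram(
    hits: pd.DataFrame | list[MotifHit],
    n_target: int,
    bin_width: int = 1,
    rng: tuple[int, int] = (-150, 100),
) -> pd.DataFrame:
    """Occurrence-level motif density, reported as motifs per bp per TSS."""
    if n_target <= 0:
        raise ValueError("n_target must be > 0")
    if isinstance(hits, list):
        hits = hits_to_frame(hits)
    lo, hi = rng
    edges = np.arange(lo, hi + bin_width + 1, bin_width)
    counts, _ = np.histogram(hits["rel_pos"].to_numpy() if len(hits) else [],
                             bins=edges)
    return pd.DataFrame({
        "position": edges[:-1],
        "density": counts / (bin_width * n_target),
    })


# ---------------------------------------------------------------------------
# Headline pipeline


def enrichment_with_matched_background(
    targets,
    pool,
    motif_library: list[PWM],
    rng: tuple[int, int] = (-150, 100),
    width: int = 30,
    step: int = 10,
    k: int = 2,
    n_bins: int = 10,
    seed: int | None = None,
    strand_mode: str = "both",
    n_select: int | None = None,
    up: int | None = None,
) -> tuple[EnrichmentMap, dict]:
    """Matched-background selection + PWM scanning + windowed Fisher tests.

    ``targets``/``pool`` may be AnchoredWindow lists or encoded matrices (in
    which case ``up`` gives the upstream extent so hit positions are
    anchor-relative).  Returns the enrichment map plus diagnostics
    (selected pool indices and the convergence trace).
    """
    tmat = bg._as_matrix(targets)
    pmat = bg._as_matrix(pool)
    if up is None:
        up = targets[0].up if (len(targets)
                               and isinstance(targets[0], AnchoredWindow)) else 0
    sel, trace = bg.select_matched_background(
        tmat, pmat, k=k, n_bins=n_bins, n_select=n_select, seed=seed)
    bmat = pmat[sel]

    grid = grid_windows(rng, width, step)
    lo, hi = rng

    def _cell_counts(mat: np.ndarray, hits: pd.DataFrame) -> list[int]:
        # boolean (n, range) matrix of hit centers, then any() per window
        mask = np.zeros((len(mat), hi - lo + 1), dtype=bool)
        inside = hits[(hits["rel_pos"] >= lo) & (hits["rel_pos"] <= hi)]
        mask[inside["seq_index"].to_numpy(),
             inside["rel_pos"].to_numpy() - lo] = True
        return [int(mask[:, ws - lo : we - lo + 1].any(axis=1).sum())
                for ws, we in grid]

    rows = []
    for pwm in motif_library:
        t_hits = hit_centers(tmat, pwm, strand_mode, up=up)
        b_hits = hit_centers(bmat, pwm, strand_mode, up=up)
        strands = (["sense", "antisense"] if strand_mode == "separate"
                   else [strand_mode])
        for strand in strands:
            if strand_mode == "separate":
                tsub = t_hits[t_hits["strand_of_hit"] == strand]
                bsub = b_hits[b_hits["strand_of_hit"] == strand]
            else:
                tsub, bsub = t_hits, b_hits
            ta = _cell_counts(tmat, tsub)
            bb = _cell_counts(bmat, bsub)
            for (ws, we), a, b in zip(grid, ta, bb):
                rows.append((pwm.name, strand, ws, we, a, b))
    table = pd.DataFrame(
        rows, columns=["motif", "strand", "window_start", "window_end",
                       "target_count", "background_count"])
    emap = _finalize_map(table, grid, len(tmat), len(bmat))
    return emap, {"selected": sel, "trace": trace}
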