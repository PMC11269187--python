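"""Position-dependent association between motif-altering variants and TSS activity.

The idea: orient each SNV near a TSS so one allele is "active" (associated
with higher initiation) and the other "inactive", compute the change in
motif log-odds score (active - inactive) for variants falling inside motif
matches, and compare the observed change distribution per TSS-distance
window against a null built by saturation mutagenesis.  The null preserves
the position and nucleotide identity of the observed variants: every
possible substitution of every sequence is scored, and each (position,
ref->alt) substitution class is weighted by how often that class was
actually observed.  Observed and expected distributions are compared with a
weighted Mann-Whitney U-test; positive signed log10 P_adj means the active
allele carries the stronger motif (activator-like behaviour at that
distance), negative means repressor-like.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seqmodel import PWM, AnchoredWindow, encode
from . import background as bg
from .enrichment import benjamini_hochberg, grid_windows, P_FLOOR

logger = logging.getLogger("tssgrammar")

_NEG = -1e4  # finite sentinel for impossible placements (N bases); far below
# any detection threshold, so such placements can never become eligible.

_BASES = "ACGT"


@dataclass
class VariantObservation:
    """One oriented SNV near a TSS."""

    variant_id: str
    window_id: str
    rel_pos: int
    ref: str
    alt: str
    active: str  # 'ref' or 'alt'
    source: str = "tssQTL"


# ---------------------------------------------------------------------------
# Orientation assignment


def assign_orientation(
    variants: pd.DataFrame,
    activity: pd.DataFrame,
    mode: str = "qtl",
    slope_threshold: float = 0.1,
    p_threshold: float = 0.25,
) -> tuple[pd.DataFrame, dict]:
    """Assign active/inactive alleles and drop variants failing thresholds.

    qtl mode: ``activity`` has columns (variant_id, slope, p); a variant is
    kept iff |slope| > slope_threshold and p < p_threshold, and the active
    allele is alt for positive slopes, ref for negative ones.

    strain mode: ``activity`` has columns (window_id, log2fc, p_adj) from an
    external differential analysis; kept iff p_adj < p_threshold, active =
    alt when log2fc > 0 (alt allele taken as the higher-activity strain's).

    Returns the oriented variant table plus drop counts.
    """
    required = {"variant_id", "window_id", "rel_pos", "ref", "alt"}
    if not required <= set(variants.columns):
        raise ValueError(f"variants need columns {sorted(required)}")
    n_in = len(variants)
    if mode == "qtl":
        merged = variants.merge(activity[["variant_id", "slope", "p"]],
                                on="variant_id", how="inner")
        keep = (merged["slope"].abs() > slope_threshold) & \
               (merged["p"] < p_threshold)
        merged = merged[keep].copy()
        merged["active"] = np.where(merged["slope"] > 0, "alt", "ref")
    elif mode == "strain":
        merged = variants.merge(activity[["window_id", "log2fc", "p_adj"]],
                                on="window_id", how="inner")
        merged = merged[merged["p_adj"] < p_threshold].copy()
        merged["active"] = np.where(merged["log2fc"] > 0, "alt", "ref")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    counts = {"input": n_in, "retained": len(merged),
              "dropped": n_in - len(merged)}
    logger.info("orientation: retained %d of %d variants", len(merged), n_in)
    return merged.reset_index(drop=True), counts


# ---------------------------------------------------------------------------
# Saturation mutagenesis delta records


def saturation_delta_records(
    mat: np.ndarray, pwm: PWM, up: int = 0
) -> pd.DataFrame:
    """All (sequence, position, substitution) motif-score deltas with an
    above-threshold match in at least one allele, on both strands.

    Columns: seq_index, rel_pos, from_base, to_base, center (motif center,
    anchor-relative), pair_max (best of the two allele scores at that
    placement) and delta = score(to) - score(from).  Downstream tests pick,
    per substitution and per distance interval, the best-scoring placement
    whose center lies in the interval.
    """
    frames = []
    for label, p in (("sense", pwm), ("antisense", pwm.reverse_complement())):
        lo = np.where(np.isfinite(p.log_odds), p.log_odds, _NEG)
        lo = np.concatenate([lo, np.full((len(p), 1), _NEG)], axis=1)
        n, L = mat.shape
        n_off = L - len(p) + 1
        if n_off <= 0:
            continue
        S = np.zeros((n, n_off))
        for j in range(len(p)):
            S += lo[j, mat[:, j : j + n_off]]
        c = p.center_index
        thr = pwm.detection_threshold
        for j in range(len(p)):
            orig = mat[:, j : j + n_off]  # base under motif column j, per offset
            base_contrib = lo[j, orig]
            for b in range(4):
                d = lo[j, b] - base_contrib
                s_alt = S + d
                elig = (np.maximum(S, s_alt) >= thr) & (orig != b) & (orig < 4)
                if not elig.any():
                    continue
                si, off = np.where(elig)
                frames.append(pd.DataFrame({
                    "seq_index": si,
                    "rel_pos": off + j - up,
                    "from_base": orig[si, off],
                    "to_base": b,
                    "center": off + c - up,
                    "pair_max": np.maximum(S, s_alt)[si, off],
                    "delta": d[si, off],
                }))
    if not frames:
        return pd.DataFrame(columns=["seq_index", "rel_pos", "from_base",
                                     "to_base", "center", "pair_max", "delta"])
    return pd.concat(frames, ignore_index=True)


def _best_in_interval(records: pd.DataFrame, interval: tuple[int, int]
                      ) -> pd.DataFrame:
    """Best-scoring placement per (seq, position, substitution) with the
    motif center inside the closed interval."""
    lo, hi = interval
    sub = records[(records["center"] >= lo) & (records["center"] <= hi)]
    if sub.empty:
        return sub
    idx = sub.groupby(["seq_index", "rel_pos", "from_base", "to_base"],
                      sort=False)["pair_max"].idxmax()
    return sub.loc[idx]


# ---------------------------------------------------------------------------
# Observed and expected delta distributions


def observed_motif_deltas(
    oriented: pd.DataFrame,
    windows,
    pwm: PWM,
    interval: tuple[int, int],
    up: int | None = None,
    records: pd.DataFrame | None = None,
    id_to_index: dict | None = None,
) -> np.ndarray:
    """Motif score deltas (active - inactive) for oriented variants whose
    position overlaps an above-threshold motif match (in either allele) with
    the motif center inside ``interval``.

    The best-scoring overlapping placement is used when several overlap.
    Indels are not supported (single-base ref/alt only).
    """
    mat, up, id_to_index = _windows_and_index(windows, up, id_to_index)
    if records is None:
        records = saturation_delta_records(mat, pwm, up=up)
    best = _best_in_interval(records, interval)
    if best.empty or oriented.empty:
        return np.zeros(0)

    v = oriented.copy()
    snv = (v["ref"].str.len() == 1) & (v["alt"].str.len() == 1)
    n_indel = int((~snv).sum())
    if n_indel:
        logger.info("skipping %d non-SNV variants", n_indel)
        v = v[snv]
    v["seq_index"] = v["window_id"].map(id_to_index)
    v = v.dropna(subset=["seq_index"])
    v["seq_index"] = v["seq_index"].astype(int)
    v["to_base"] = v["alt"].map({b: i for i, b in enumerate(_BASES)})
    merged = v.merge(
        best[["seq_index", "rel_pos", "from_base", "to_base", "delta"]],
        on=["seq_index", "rel_pos", "to_base"], how="inner")
    # records' from_base is the window (reference) base; sanity-check refs
    ref_idx = merged["ref"].map({b: i for i, b in enumerate(_BASES)})
    merged = merged[merged["from_base"] == ref_idx]
    sign = np.where(merged["active"] == "alt", 1.0, -1.0)
    return (sign * merged["delta"].to_numpy()).astype(float)


def expected_delta_distribution(
    windows,
    pwm: PWM,
    variant_type_counts: pd.DataFrame,
    interval: tuple[int, int],
    up: int | None = None,
    records: pd.DataFrame | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Saturation-mutagenesis expected distribution of motif score deltas.

    ``variant_type_counts`` has columns (rel_pos, from_base, to_base, count)
    with bases in inactive -> active orientation, i.e. the counts of
    observed variant classes per position.  Every window receiving that
    substitution contributes its delta; each class's total weight equals its
    observed count (split equally across contributing windows), which scales
    the saturation scan by the observed variant spectrum.

    Returns (values, weights); empty arrays when nothing is eligible.
    """
    mat, up, _ = _windows_and_index(windows, up, None)
    if records is None:
        records = saturation_delta_records(mat, pwm, up=up)
    best = _best_in_interval(records, interval)
    counts = variant_type_counts[variant_type_counts["count"] > 0]
    if best.empty or counts.empty:
        return np.zeros(0), np.zeros(0)
    merged = best.merge(counts, on=["rel_pos", "from_base", "to_base"],
                        how="inner")
    if merged.empty:
        return np.zeros(0), np.zeros(0)
    group_sizes = merged.groupby(["rel_pos", "from_base", "to_base"],
                                 sort=False)["delta"].transform("size")
    weights = merged["count"].to_numpy() / group_sizes.to_numpy()
    return merged["delta"].to_numpy().astype(float), weights.astype(float)


def variant_type_counts(oriented: pd.DataFrame) -> pd.DataFrame:
    """Counts of observed substitution classes per relative position, in
    inactive -> active orientation."""
    b2i = {b: i for i, b in enumerate(_BASES)}
    v = oriented.copy()
    ref_i = v["ref"].map(b2i)
    alt_i = v["alt"].map(b2i)
    active_alt = v["active"] == "alt"
    v["from_base"] = np.where(active_alt, ref_i, alt_i)
    v["to_base"] = np.where(active_alt, alt_i, ref_i)
    out = (v.groupby(["rel_pos", "from_base", "to_base"])
           .size().rename("count").reset_index())
    return out


# ---------------------------------------------------------------------------
# Weighted Mann-Whitney U


def weighted_mannwhitney(
    x: np.ndarray, values: np.ndarray, weights: np.ndarray
) -> tuple[float, float, int]:
    """Rank-sum test of sample ``x`` against a weighted empirical sample.

    U accumulates the weights of expected values below each observation
    (ties count half-weight).  Each weighted value is treated as an
    independent (fractional) pseudo-observation: the null variance is
    Var(U) = n1/12 * (W^2 + (n1+1) * sum(w^2)), scaled by a tie factor on
    pooled weights, with a 0.5 continuity correction.  With unit weights
    this is exactly the tie-corrected classical Mann-Whitney U; with many
    small weights it approaches the fixed-distribution limit, which is what
    keeps P-values uniform when observations are drawn from the expected
    distribution itself.

    Returns (U, two-sided p, sign) with sign +1 when x is stochastically
    larger than the weighted sample.
    """
    x = np.asarray(x, dtype=float)
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n1 = len(x)
    W = weights.sum()
    if n1 == 0 or W <= 0:
        raise ValueError("both samples must be non-empty")
    order = np.argsort(values, kind="stable")
    v_sorted = values[order]
    w_sorted = weights[order]
    cum = np.concatenate([[0.0], np.cumsum(w_sorted)])
    lo = np.searchsorted(v_sorted, x, side="left")
    hi = np.searchsorted(v_sorted, x, side="right")
    U = float((cum[lo] + 0.5 * (cum[hi] - cum[lo])).sum())

    mu = n1 * W / 2.0
    N = n1 + W
    # Exact null variance for a weighted second sample:
    # Var(U) = n1/12 * (W^2 + (n1+1) * sum(w^2)), scaled by a tie factor
    # computed on pooled weights.  With unit weights this is exactly the
    # tie-corrected classical Mann-Whitney variance; with many small
    # weights it approaches the fixed-distribution limit n1*W^2*(1-sum p^3)/12.
    pooled = np.concatenate([x, values])
    pooled_w = np.concatenate([np.ones(n1), weights])
    uniq, pinv = np.unique(pooled, return_inverse=True)
    t = np.bincount(pinv, weights=pooled_w)
    tie_factor = (t ** 3 - t).sum() / ((N - 1) * N * (N + 1))
    var = n1 / 12.0 * (W ** 2 + (n1 + 1) * (weights ** 2).sum()) \
        * (1.0 - tie_factor)
    if var <= 0:
        return U, 1.0, 1
    z = (U - mu - 0.5 * np.sign(U - mu)) / np.sqrt(var)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return U, p, (1 if U >= mu else -1)


# ---------------------------------------------------------------------------
# Positional association map


def positional_association_test(
    oriented: pd.DataFrame,
    windows,
    pwm: PWM,
    rng: tuple[int, int] = (-150, 100),
    width: int = 30,
    step: int = 10,
    min_obs: int = 10,
    up: int | None = None,
) -> pd.DataFrame:
    """Signed log10 adjusted P per distance window for one motif.

    For each window of the grid the observed (active - inactive) motif score
    deltas are compared against the saturation-mutagenesis expected
    distribution (weighted by the globally observed variant spectrum) with a
    weighted Mann-Whitney U-test.  Windows with fewer than ``min_obs``
    observed deltas are not tested.  BH correction is applied across all
    tested windows; signed_logP > 0 indicates activator-like behaviour
    (weakened motif on the inactive allele).
    """
    mat, up, id_to_index = _windows_and_index(windows, up, None)
    records = saturation_delta_records(mat, pwm, up=up)
    counts = variant_type_counts(oriented)
    rows = []
    for ws, we in grid_windows(rng, width, step):
        obs = observed_motif_deltas(oriented, mat, pwm, (ws, we), up=up,
                                    records=records, id_to_index=id_to_index)
        if len(obs) < min_obs:
            rows.append((pwm.name, ws, we, len(obs), np.nan, np.nan, 0))
            continue
        exp_v, exp_w = expected_delta_distribution(
            mat, pwm, counts, (ws, we), up=up, records=records)
        if len(exp_v) == 0:
            rows.append((pwm.name, ws, we, len(obs), np.nan, np.nan, 0))
            continue
        U, p, sign = weighted_mannwhitney(obs, exp_v, exp_w)
        rows.append((pwm.name, ws, we, len(obs), U, p, sign))
    table = pd.DataFrame(rows, columns=["motif", "window_start", "window_end",
                                        "n_observed", "U", "p", "sign"])
    tested = table["p"].notna()
    padj = np.full(len(table), np.nan)
    if tested.any():
        padj[tested.to_numpy()] = benjamini_hochberg(table.loc[tested, "p"])
    table["p_adj"] = padj
    table["signed_logP"] = table["sign"] * -np.log10(
        np.maximum(table["p_adj"].fillna(1.0), P_FLOOR))
    return table


# ---------------------------------------------------------------------------
# Input plumbing


def _windows_and_index(windows, up, id_to_index):
    if isinstance(windows, np.ndarray):
        mat = windows
        up = 0 if up is None else up
        if id_to_index is None:
            id_to_index = {str(i): i for i in range(len(mat))}
    else:
        mat = bg._as_matrix(windows)
        if up is None:
            up = windows[0].up if (len(windows) and isinstance(
                windows[0], AnchoredWindow)) else 0
        if id_to_index is None:
            id_to_index = {w.window_id: i for i, w in enumerate(windows)} \
                if (len(windows) and isinstance(windows[0], AnchoredWindow)) \
                else {str(i): i for i in range(len(mat))}
    return mat, up, id_to_index


def read_vcf_minimal(path) -> pd.DataFrame:
    """Minimal VCF reader: CHROM, POS (1-based), ID, REF, ALT; site-only or
    single-sample files; non-SNV rows are kept but flagged by allele length."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 5:
                continue
            rows.append((f[0], int(f[1]), f[2], f[3].upper(), f[4].upper()))
    return pd.DataFrame(rows, columns=["chrom", "pos", "variant_id", "ref",
                                       "alt"])


def map_variants_to_windows(
    vcf: pd.DataFrame,
    windows: list[AnchoredWindow],
    cis_range: int = 200,
) -> pd.DataFrame:
    """Attach each variant to its nearest TSS window within ``cis_range`` bp.

    Produces window-oriented rel_pos and alleles (complemented for minus
    strand windows); variants with no proximal TSS are dropped and counted.
    """
    comp = str.maketrans("ACGTN", "TGCAN")
    out = []
    dropped = 0
    by_chrom: dict[str, list[AnchoredWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for row in vcf.itertuples(index=False):
        cands = by_chrom.get(row.chrom, [])
        best, best_d = None, None
        for w in cands:
            d = abs(row.pos - 1 - w.anchor)
            if d <= cis_range and (best_d is None or d < best_d):
                best, best_d = w, d
        if best is None:
            dropped += 1
            continue
        g = row.pos - 1
        if best.strand == "+":
            rel = g - best.anchor
            ref, alt = row.ref, row.alt
        else:
            rel = best.anchor - g
            ref, alt = row.ref.translate(comp), row.alt.translate(comp)
        if not (-best.up <= rel <= best.down):
            dropped += 1
            continue
        out.append((row.variant_id, best.window_id, rel, ref, alt))
    if dropped:
        logger.info("dropped %d variants without a proximal TSS", dropped)
    return pd.DataFrame(out, columns=["variant_id", "window_id", "rel_pos",
                                      "ref", "alt"])
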