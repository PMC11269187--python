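"""Positional analytics over motif hits and activity scores.

Covers four analyses that read positional structure out of TSS-anchored
data: Fourier power spectra of binding-site density (DNA helical
periodicity), motif-enrichment positional profiles linking per-position
motif scores to sequence activity while controlling for GC content,
initiator-element stratification, and TF-TF spacing matrices of initiation
signal sorted by pairwise binding-site offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqmodel import PWM, AnchoredWindow, classify_inr, gc_fraction_matrix
from . import background as bg
from .enrichment import _offset_scores, hit_centers

logger = logging.getLogger("tssgrammar")

DEFAULT_PERIOD_GRID = np.round(np.arange(0.1, 50.0 + 1e-9, 0.1), 1)


@dataclass
class PowerSpectrum:
    """Normalized Fourier power per period (bp); max power scaled to 1
    unless the input density was constant (then flagged, all-zero)."""

    periods: np.ndarray
    power: np.ndarray
    flagged_constant: bool = False

    @property
    def dominant_period(self) -> float:
        return float(self.periods[np.argmax(self.power)])


@dataclass
class MeppProfile:
    """Per-position partial Pearson correlation between motif log-odds and
    sequence score, controlling for GC fraction."""

    positions: np.ndarray
    partial_r: np.ndarray
    flags: np.ndarray  # True where x had zero variance (r reported as 0)
    hit_table: pd.DataFrame


def power_spectrum(
    density: np.ndarray,
    positions: np.ndarray | None = None,
    period_grid: np.ndarray | None = None,
) -> PowerSpectrum:
    """Direct Fourier power of a positional density over a period grid.

    The density is mean-subtracted, then power(T) = |sum_x d(x) e^(-2pi i x/T)|^2
    is evaluated per period and normalized to a maximum of 1.  The default
    grid covers periods (0, 50] bp in 0.1 bp increments; a constant density
    gives a flagged all-zero spectrum (normalization skipped).
    """
    d = np.asarray(density, dtype=float)
    if d.size < 16:
        raise ValueError("density must cover at least 16 positions")
    x = np.arange(d.size) if positions is None else np.asarray(positions, float)
    if x.size != d.size:
        raise ValueError("positions and density lengths differ")
    if np.any(np.diff(x) != x[1] - x[0]):
        raise ValueError("density must be on a contiguous regular grid")
    periods = DEFAULT_PERIOD_GRID if period_grid is None \
        else np.asarray(period_grid, float)
    if (periods <= 0).any():
        raise ValueError("periods must be positive")
    dc = d - d.mean()
    phase = np.exp(-2j * np.pi * x[None, :] / periods[:, None])
    power = np.abs(phase @ dc) ** 2
    mx = power.max()
    # constant densities leave only floating-point residue after mean
    # subtraction; compare against the density's own scale
    if mx <= 1e-20 * max(1.0, float((d ** 2).sum())):
        logger.warning("constant density: zero power spectrum, not normalized")
        return PowerSpectrum(periods, np.zeros_like(power), flagged_constant=True)
    return PowerSpectrum(periods, power / mx)


# ---------------------------------------------------------------------------
# Positional partial-correlation profile (motif enrichment positional
# profile, "mepp")


def partial_pearson(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """First-order partial correlation r_xy.z."""
    rxy = np.corrcoef(x, y)[0, 1]
    rxz = np.corrcoef(x, z)[0, 1]
    ryz = np.corrcoef(y, z)[0, 1]
    denom = np.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))
    if denom == 0:
        return 0.0
    return float((rxy - rxz * ryz) / denom)


def mepp_profile(
    windows,
    scores: np.ndarray,
    pwm: PWM,
    up: int | None = None,
) -> MeppProfile:
    """Positional motif-enrichment profile against per-sequence scores.

    At each anchor-relative position p the motif is placed with its center
    at p; x_i is the resulting log2-odds in window i (-inf from N bases or
    impossible placements is clamped to the finite dataset minimum), y_i the
    sequence score and z_i the window GC fraction.  The profile reports the
    first-order partial Pearson correlation r_xy.z per position; positions
    with zero variance in x are flagged and reported as 0.
    """
    mat = bg._as_matrix(windows)
    if up is None:
        up = windows[0].up if (len(windows)
                               and isinstance(windows[0], AnchoredWindow)) else 0
    y = np.asarray(scores, dtype=float)
    if len(y) != len(mat):
        raise ValueError("scores and windows lengths differ")
    if len(y) < 10:
        raise ValueError("need at least 10 scored windows")
    if y.std() == 0:
        raise ValueError("scores have zero variance")

    S = _offset_scores(mat, pwm)  # (n, n_off), offset = window start of motif
    c = pwm.center_index
    finite = S[np.isfinite(S)]
    clamp = finite.min() if finite.size else 0.0
    S = np.where(np.isfinite(S), S, clamp)

    z = gc_fraction_matrix(mat)
    positions = np.arange(S.shape[1]) + c - up
    r = np.zeros(S.shape[1])
    flags = np.zeros(S.shape[1], dtype=bool)
    for j in range(S.shape[1]):
        x = S[:, j]
        if x.std() <= 1e-9 * (1.0 + np.abs(x).mean()):
            flags[j] = True
            continue
        r[j] = partial_pearson(x, y, z)
    hit_table = hit_centers(mat, pwm, "both", up=up)
    return MeppProfile(positions=positions, partial_r=r, flags=flags,
                       hit_table=hit_table)


# ---------------------------------------------------------------------------
# TF-TF spacing


def pair_spacing_matrix(
    regions,
    pwm_a: PWM,
    pwm_b: PWM,
    signal: np.ndarray,
    flank: int = 300,
    up: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Initiation signal around non-redundant A sites, sorted by B-A offset.

    ``regions`` are windows covering +/-``flank`` around region centers;
    ``signal`` is per-region per-position initiation counts on the same
    coordinates.  Non-redundant A hits are chosen greedily by descending
    score with an exclusion radius of one motif length; each co-occurring B
    hit within +/-``flank`` of an A hit contributes one row (a region with
    several B hits appears once per B hit).  Rows are sorted by the B-A
    offset; the returned matrix holds the per-position signal re-centered on
    the A hit.
    """
    mat = bg._as_matrix(regions)
    if up is None:
        up = regions[0].up if (len(regions)
                               and isinstance(regions[0], AnchoredWindow)) else \
            mat.shape[1] // 2
    signal = np.asarray(signal, dtype=float)
    if signal.shape != mat.shape:
        raise ValueError("signal must align with regions (same shape)")

    a_hits = hit_centers(mat, pwm_a, "both", up=up)
    b_hits = hit_centers(mat, pwm_b, "both", up=up)

    rows = []
    L = mat.shape[1]
    for seq_i, grp in a_hits.groupby("seq_index"):
        kept: list[tuple[int, float]] = []
        for r in grp.sort_values("score", ascending=False).itertuples(index=False):
            if all(abs(r.rel_pos - pos) >= len(pwm_a) for pos, _ in kept):
                kept.append((int(r.rel_pos), float(r.score)))
        bsub = b_hits[b_hits["seq_index"] == seq_i]
        for a_pos, a_score in kept:
            for rb in bsub.itertuples(index=False):
                offset = int(rb.rel_pos) - a_pos
                if abs(offset) <= flank:
                    rows.append((int(seq_i), a_pos, int(rb.rel_pos), offset,
                                 a_score, float(rb.score)))
    table = pd.DataFrame(
        rows, columns=["region", "a_pos", "b_pos", "offset", "a_score",
                       "b_score"])
    if table.empty:
        logger.warning("no A/B co-occurrences within +/-%d bp", flank)
        return table, np.zeros((0, 2 * flank + 1))
    table = table.sort_values(["offset", "region"], kind="stable",
                              ignore_index=True)
    matrix = np.zeros((len(table), 2 * flank + 1))
    for i, r in enumerate(table.itertuples(index=False)):
        a_col = r.a_pos + up  # column index of the A center
        src_lo, src_hi = max(0, a_col - flank), min(L, a_col + flank + 1)
        dst_lo = src_lo - (a_col - flank)
        matrix[i, dst_lo : dst_lo + (src_hi - src_lo)] = \
            signal[r.region, src_lo:src_hi]
    return table, matrix


def stratify_by_inr(windows: list[AnchoredWindow]
                    ) -> dict[str, list[AnchoredWindow]]:
    """Partition windows by presence of the initiator element (BBCA+1BW)."""
    out: dict[str, list[AnchoredWindow]] = {"inr": [], "non_inr": []}
    for w in windows:
        out["inr" if classify_inr(w) else "non_inr"].append(w)
    return out
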