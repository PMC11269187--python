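"""Positionally matched background selection and synthetic background generation.

Motif enrichment at TSS-anchored windows is confounded by two sequence
biases: the overall GC content of regulatory regions and strong
position-dependent nucleotide preferences near the initiating base.  This
module builds background sets that reproduce both: candidate sequences are
first GC-binned against the targets' per-sequence GC distribution, then an
iterative descent progressively removes candidates inside each bin until
the per-position k-mer frequencies of the remaining background match the
targets'.  A position-dependent Markov generator is provided as an
alternative, fully synthetic background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqmodel import AnchoredWindow, encode_matrix, gc_fraction_matrix

logger = logging.getLogger("tssgrammar")


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class PositionalKmerProfile:
    """Per-position distribution over the 4^k k-mers starting at each position.

    ``freq`` has shape (length - k + 1, 4**k); each row sums to 1 over the
    k-mers observed at that position (k-mers containing N are excluded from
    both numerator and denominator).
    """

    k: int
    length: int
    freq: np.ndarray

    def __post_init__(self) -> None:
        expected = (self.length - self.k + 1, 4 ** self.k)
        if self.freq.shape != expected:
            raise ValueError(f"freq shape {self.freq.shape} != {expected}")

    @property
    def n_positions(self) -> int:
        return self.freq.shape[0]


@dataclass
class GCBinning:
    """Quantile-based GC bins: edges partition [0, 1]; every sequence gets one bin."""

    n_bins: int
    edges: np.ndarray  # length n_bins + 1, edges[0] = 0, edges[-1] = 1
    assignment: np.ndarray  # per-sequence bin index in [0, n_bins)

    def assign(self, gc: np.ndarray) -> np.ndarray:
        """Assign new GC fractions to the existing bins."""
        return np.clip(np.searchsorted(self.edges[1:-1], gc, side="right"),
                       0, self.n_bins - 1)


# ---------------------------------------------------------------------------
# Profiles and binning


def _as_matrix(seqs) -> np.ndarray:
    if isinstance(seqs, np.ndarray):
        return seqs
    if len(seqs) and isinstance(seqs[0], AnchoredWindow):
        return encode_matrix([w.seq for w in seqs])
    return encode_matrix(list(seqs))


def _kmer_index(mat: np.ndarray, k: int) -> np.ndarray:
    """(n, L-k+1) k-mer index per start position; 4**k marks k-mers with N."""
    n, L = mat.shape
    n_pos = L - k + 1
    idx = np.zeros((n, n_pos), dtype=np.int32)
    bad = np.zeros((n, n_pos), dtype=bool)
    for j in range(k):
        col = mat[:, j : j + n_pos]
        idx = idx * 4 + np.minimum(col, 3).astype(np.int32)
        bad |= col == 4
    idx[bad] = 4 ** k
    return idx


def _kmer_counts(kidx: np.ndarray, n_kmers: int) -> np.ndarray:
    """(n_pos, n_kmers) counts from a k-mer index matrix (N slot dropped)."""
    n, n_pos = kidx.shape
    flat = (np.arange(n_pos, dtype=np.int64) * (n_kmers + 1))[None, :] + kidx
    counts = np.bincount(flat.ravel(), minlength=n_pos * (n_kmers + 1))
    return counts.reshape(n_pos, n_kmers + 1)[:, :n_kmers].astype(float)


def _counts_to_freq(counts: np.ndarray) -> np.ndarray:
    denom = counts.sum(axis=1, keepdims=True)
    return counts / np.maximum(denom, 1e-300)


def positional_kmer_profile(windows, k: int = 2) -> PositionalKmerProfile:
    """Empirical per-position k-mer frequency profile of equal-length windows."""
    if k < 1:
        raise ValueError("k must be >= 1")
    mat = _as_matrix(windows)
    if mat.shape[1] < k:
        raise ValueError("windows shorter than k")
    kidx = _kmer_index(mat, k)
    freq = _counts_to_freq(_kmer_counts(kidx, 4 ** k))
    return PositionalKmerProfile(k=k, length=mat.shape[1], freq=freq)


def assign_gc_bins(sequences, n_bins: int = 10) -> GCBinning:
    """Split sequences into ``n_bins`` equal-count bins by per-sequence GC.

    Bin edges are GC quantiles of the input; degenerate inputs (fewer
    sequences than bins, or all-identical GC) collapse bins with a warning.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    mat = _as_matrix(sequences)
    gc = gc_fraction_matrix(mat)
    if len(gc) < n_bins:
        logger.warning("fewer sequences (%d) than bins (%d); bins collapse",
                       len(gc), n_bins)
    inner = np.quantile(gc, np.linspace(0, 1, n_bins + 1)[1:-1]) if n_bins > 1 \
        else np.array([])
    edges = np.concatenate([[0.0], inner, [1.0]])
    binning = GCBinning(n_bins=n_bins, edges=edges, assignment=np.zeros(0, int))
    # the defining set is split into exactly equal-count bins by stable rank
    # (ties broken by input order); the edges serve to assign other sets
    if np.unique(gc).size == 1:
        logger.warning("all sequences share one GC value: single occupied bin")
        binning.assignment = np.zeros(len(gc), dtype=int)
        return binning
    order = np.argsort(gc, kind="stable")
    assignment = np.empty(len(gc), dtype=int)
    assignment[order] = np.arange(len(gc)) * n_bins // max(len(gc), 1)
    binning.assignment = assignment
    occupied = np.unique(binning.assignment).size
    if occupied < n_bins:
        logger.warning("only %d of %d GC bins occupied", occupied, n_bins)
    return binning


# ---------------------------------------------------------------------------
# Matched background selection


def _score_sequences(kidx: np.ndarray, diff: np.ndarray) -> np.ndarray:
    """Per-sequence linear combination of the frequency differences of the
    k-mers the sequence contains at each position (N k-mers contribute 0)."""
    n_pos, n_kmers = diff.shape
    padded = np.concatenate([diff, np.zeros((n_pos, 1))], axis=1)
    return padded[np.arange(n_pos)[None, :], kidx].sum(axis=1)


def _kde(values: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Kernel-smoothed histogram density (Gaussian kernel, Silverman
    bandwidth) of ``values``, evaluated at ``points``."""
    n = len(values)
    sd = values.std()
    if sd == 0 or n < 2:
        return np.ones_like(points, dtype=float)
    bw = 1.06 * sd * n ** (-1 / 5)
    lo = min(values.min(), points.min()) - 3 * bw
    hi = max(values.max(), points.max()) + 3 * bw
    nb = 256
    width = (hi - lo) / nb
    hist, _ = np.histogram(values, bins=nb, range=(lo, hi))
    r = max(1, int(np.ceil(3 * bw / width)))
    xs = np.arange(-r, r + 1) * width
    kernel = np.exp(-0.5 * (xs / bw) ** 2)
    kernel /= kernel.sum() * width
    dens = np.convolve(hist / n, kernel, mode="same")
    bins = np.clip(((points - lo) / width).astype(int), 0, nb - 1)
    return np.maximum(dens[bins], 0.0)


def _weighted_subsample(rng: np.random.Generator, idx: np.ndarray,
                        weights: np.ndarray, size: int) -> np.ndarray:
    """Weighted sampling without replacement via the Gumbel top-k trick."""
    w = np.maximum(weights, 1e-12)
    keys = np.log(w) + rng.gumbel(size=len(w))
    keep = np.argpartition(-keys, size - 1)[:size]
    return idx[keep]


def select_matched_background(
    targets,
    pool,
    k: int = 2,
    n_bins: int = 10,
    n_select: int | None = None,
    max_iter: int = 100,
    seed: int | None = None,
    tol: float | None = None,
    shrink: float = 0.9,
    polish_passes: int = 300,
) -> tuple[np.ndarray, list[float]]:
    """Select pool sequences matching the targets' GC and positional k-mer content.

    Within each target-GC-quantile bin, the candidate background is reduced
    by an iterative descent: each iteration computes the per-position k-mer
    frequency difference (target - background), scores every sequence by the
    summed differences of the k-mers it contains, and randomly removes
    candidates so that the retained score distribution tracks the targets'
    (importance weights from kernel density estimates of the two score
    distributions).  Once the requested size is reached, a batched exchange
    stage swaps selected/reserve candidates while the swap reduces the L1
    frequency difference.

    Returns ``(selected_pool_indices, trace)`` where ``trace`` is the total
    L1 k-mer frequency difference per iteration.

    ``seed`` is mandatory: the selection is stochastic and must be
    reproducible.
    """
    if seed is None:
        raise ValueError("seed is mandatory for reproducible background selection")
    rng = np.random.default_rng(seed)

    tmat, pmat = _as_matrix(targets), _as_matrix(pool)
    if tmat.shape[1] != pmat.shape[1]:
        raise ValueError("pool windows must have the same length as targets")
    n_targets, L = tmat.shape
    n_select = 2 * n_targets if n_select is None else n_select
    if len(pmat) < n_select:
        raise ValueError(f"pool size {len(pmat)} < n_select {n_select}")
    if tol is None:
        tol = 0.01 * L

    n_kmers = 4 ** k
    tkidx = _kmer_index(tmat, k)
    pkidx = _kmer_index(pmat, k)
    binning = assign_gc_bins(tmat, n_bins)
    # edge-based assignment for both sets so tied GC values land on the same
    # side for targets and pool alike
    tgt_bins = binning.assign(gc_fraction_matrix(tmat))
    pool_gc = gc_fraction_matrix(pmat)
    pool_bins = binning.assign(pool_gc)

    # per-bin quota proportional to target occupancy
    tgt_bin_counts = np.bincount(tgt_bins, minlength=n_bins)
    quota = np.floor(n_select * tgt_bin_counts / n_targets).astype(int)
    for i in np.argsort(-(n_select * tgt_bin_counts / n_targets - quota)):
        if quota.sum() >= n_select:
            break
        quota[i] += 1

    # candidate lists per bin; short bins borrow nearest-GC neighbours
    order_by_gc = np.argsort(pool_gc, kind="stable")
    taken = np.zeros(len(pmat), dtype=bool)
    bin_candidates: list[np.ndarray] = []
    for b in range(n_bins):
        cand = np.where((pool_bins == b) & ~taken)[0]
        if len(cand) < quota[b]:
            logger.warning(
                "GC bin %d has %d candidates for quota %d; borrowing neighbours",
                b, len(cand), quota[b],
            )
            center = (binning.edges[b] + binning.edges[b + 1]) / 2
            free = order_by_gc[~taken[order_by_gc]]
            free = free[~np.isin(free, cand)]
            extra = free[np.argsort(np.abs(pool_gc[free] - center),
                                    kind="stable")][: quota[b] - len(cand)]
            cand = np.concatenate([cand, extra])
        taken[cand] = True
        bin_candidates.append(cand)

    selected: list[np.ndarray] = []
    for b in range(n_bins):
        if quota[b] == 0:
            selected.append(np.array([], dtype=int))
            continue
        t_counts = _kmer_counts(tkidx[tgt_bins == b], n_kmers)
        t_freq = _counts_to_freq(t_counts)
        sel = _descend_bin(
            rng, t_freq, pkidx, bin_candidates[b], quota[b], max_iter, shrink,
            n_kmers, tgt_scores_idx=tkidx[tgt_bins == b],
        )
        selected.append(sel)

    cur = np.concatenate(selected).astype(int)
    reserve = np.concatenate(
        [c[~np.isin(c, s)] for c, s in zip(bin_candidates, selected)
         if len(c)] or [np.array([], dtype=int)]
    ).astype(int)
    cand_bin = np.empty(len(pmat), dtype=int)
    for b, c in enumerate(bin_candidates):
        cand_bin[c] = b
    t_freq_all = _counts_to_freq(_kmer_counts(tkidx, n_kmers))
    cur, trace = _exchange_polish(
        rng, t_freq_all, pkidx, cur, reserve, cand_bin, polish_passes,
        n_kmers, tol)
    return np.sort(cur), trace


def _descend_bin(rng, t_freq, pkidx, cur, n_sel, max_iter, shrink, n_kmers,
                 tgt_scores_idx):
    """Progressive removal inside one GC bin: resample candidates so their
    difference-score distribution tracks the targets' (importance weights
    from KDEs of the two score distributions)."""
    for _ in range(max_iter):
        if len(cur) <= n_sel:
            return cur
        bg_freq = _counts_to_freq(_kmer_counts(pkidx[cur], n_kmers))
        diff = t_freq - bg_freq
        s_bg = _score_sequences(pkidx[cur], diff)
        s_tgt = _score_sequences(tgt_scores_idx, diff)
        weights = _kde(s_tgt, s_bg) / np.maximum(_kde(s_bg, s_bg), 1e-12)
        n_next = max(n_sel, int(np.ceil(len(cur) * shrink)))
        cur = _weighted_subsample(rng, cur, weights, n_next)
    return cur


def _exchange_polish(rng, t_freq, pkidx, cur, reserve, cand_bin, passes,
                     n_kmers, tol, perturb_rounds: int = 4):
    """Exchange descent on the combined selection against the global targets.

    Swaps stay within a GC bin (preserving the matched GC distribution) but
    are scored against the global k-mer frequency difference.  Because a
    swap changes each position's k-mer counts by exactly +/-1 at fixed
    selection size, the L1 gain of a single swap is exact: per coordinate,
    adding a count is worth |d| - |d - 1/n| and removing one |d| - |d + 1/n|
    where d is the current frequency difference.  Greedy batched swaps
    descend to a single-swap local optimum; a few random within-bin
    perturbation rounds then escape plateaus, and the best configuration
    seen is returned.  The trace records the best L1 so far (monotone).
    """
    cur = cur.copy()
    reserve = reserve.copy()
    n = len(cur)
    counts = _kmer_counts(pkidx[cur], n_kmers)
    l1_prev = float(np.abs(t_freq - _counts_to_freq(counts)).sum())
    trace = [l1_prev]
    if len(reserve) == 0 or passes <= 0:
        return cur, trace
    best_cur, best_l1 = cur.copy(), l1_prev
    inv_n = 1.0 / n
    frac = 0.05
    budget = passes
    rounds_left = perturb_rounds
    while budget > 0:
        if l1_prev <= tol:
            break
        budget -= 1
        diff = t_freq - counts / n
        # exact per-coordinate L1 gain of a +1 (add) or -1 (remove) count
        gain_add = np.abs(diff) - np.abs(diff - inv_n)
        gain_rem = np.abs(diff) - np.abs(diff + inv_n)
        s_res = _score_sequences(pkidx[reserve], gain_add)
        s_sel = _score_sequences(pkidx[cur], gain_rem)
        out_list, in_list = [], []
        for b in np.unique(cand_bin[cur]):
            sel_i = np.where(cand_bin[cur] == b)[0]
            res_i = np.where(cand_bin[reserve] == b)[0]
            if len(res_i) == 0:
                continue
            k = max(1, min(int(len(sel_i) * frac), len(res_i)))
            worst = sel_i[np.argsort(-s_sel[sel_i], kind="stable")[:k]]
            best = res_i[np.argsort(-s_res[res_i], kind="stable")[:k]]
            good = s_res[best] + s_sel[worst] > 1e-12
            out_list.append(worst[good])
            in_list.append(best[good])
        stalled = not out_list or not any(len(o) for o in out_list)
        if not stalled:
            out_i = np.concatenate(out_list)
            in_i = np.concatenate(in_list)
            new_counts = (counts
                          - _kmer_counts(pkidx[cur[out_i]], n_kmers)
                          + _kmer_counts(pkidx[reserve[in_i]], n_kmers))
            l1_new = float(np.abs(t_freq - _counts_to_freq(new_counts)).sum())
            if l1_new < l1_prev - 1e-12:
                counts = new_counts
                cur[out_i], reserve[in_i] = reserve[in_i].copy(), \
                    cur[out_i].copy()
                l1_prev = l1_new
                if l1_new < best_l1:
                    best_l1 = l1_new
                    best_cur = cur.copy()
                    trace.append(l1_new)
                continue
            if frac * n >= 2:
                frac /= 2
                continue
        # Additive-score local optimum.  The additive estimate is a lower
        # bound on the exact pair gain (coordinates where the incoming and
        # outgoing sequence share a k-mer cancel exactly instead of paying
        # both penalties), so evaluate exact gains for the top candidate
        # pairs per bin and apply the improving ones.
        if rounds_left <= 0:
            break
        rounds_left -= 1
        frac = 0.05
        applied = False
        gsum = gain_add + gain_rem
        for b in np.unique(cand_bin[cur]):
            sel_i = np.where(cand_bin[cur] == b)[0]
            res_i = np.where(cand_bin[reserve] == b)[0]
            if len(res_i) == 0:
                continue
            k_out = sel_i[np.argsort(-s_sel[sel_i], kind="stable")[:40]]
            k_in = res_i[np.argsort(-s_res[res_i], kind="stable")[:40]]
            ko = pkidx[cur[k_out]]          # (ko_n, n_pos)
            ki = pkidx[reserve[k_in]]       # (ki_n, n_pos)
            pos = np.arange(ko.shape[1])
            gs_in = gsum[pos[None, :], ki]  # penalty terms at in k-mers
            used_out = np.zeros(len(k_out), bool)
            used_in = np.zeros(len(k_in), bool)
            pairs = []
            for oi in range(len(k_out)):
                shared = ko[oi][None, :] == ki  # (ki_n, n_pos)
                corr = np.where(shared, gs_in, 0.0).sum(axis=1)
                gains = s_res[k_in] + s_sel[k_out[oi]] - corr
                pairs.extend(((float(gains[ii]), oi, ii)
                              for ii in range(len(k_in))
                              if gains[ii] > 1e-12))
            for g, oi, ii in sorted(pairs, reverse=True):
                if used_out[oi] or used_in[ii]:
                    continue
                used_out[oi] = used_in[ii] = True
                o_idx, i_idx = k_out[oi], k_in[ii]
                counts += (_kmer_counts(pkidx[reserve[i_idx]][None, :],
                                        n_kmers)
                           - _kmer_counts(pkidx[cur[o_idx]][None, :],
                                          n_kmers))
                cur[o_idx], reserve[i_idx] = reserve[i_idx], cur[o_idx]
                applied = True
        if not applied:
            break
        l1_prev = float(np.abs(t_freq - _counts_to_freq(counts)).sum())
        if l1_prev < best_l1:
            best_l1 = l1_prev
            best_cur = cur.copy()
            trace.append(l1_prev)
    return best_cur, trace


# ---------------------------------------------------------------------------
# Position-dependent Markov generator


def generate_markov_background(
    profile: PositionalKmerProfile, n: int, seed: int | None = None
) -> np.ndarray:
    """Sample ``n`` synthetic sequences from a position-dependent Markov model.

    The initial k-mer is drawn from the position-0 k-mer distribution; each
    subsequent base is drawn from the conditional distribution of the k-mer
    at the next position given its (k-1)-base prefix.  Positions whose
    conditional is undefined (unseen prefix) fall back to the marginal base
    frequency at that position, with a log message.

    Returns an encoded (n, length) uint8 matrix (see seqmodel.decode_matrix).
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    rng = np.random.default_rng(seed)
    k, L = profile.k, profile.length
    freq = profile.freq
    if (freq.sum(axis=1) <= 0).any():
        raise ValueError("profile has all-zero positions")

    out = np.zeros((n, L), dtype=np.uint8)
    # initial k-mer
    p0 = freq[0] / freq[0].sum()
    first = rng.choice(4 ** k, size=n, p=p0)
    for j in range(k - 1, -1, -1):
        out[:, j] = first % 4
        first //= 4

    n_prefix = 4 ** (k - 1)
    fell_back = False
    for p in range(1, L - k + 1):
        cond = freq[p].reshape(n_prefix, 4).copy()
        row_sums = cond.sum(axis=1, keepdims=True)
        marginal = freq[p].reshape(n_prefix, 4).sum(axis=0)
        marginal = marginal / marginal.sum() if marginal.sum() > 0 \
            else np.full(4, 0.25)
        undefined = row_sums[:, 0] <= 0
        if undefined.any():
            fell_back = True
            cond[undefined] = marginal
            row_sums = cond.sum(axis=1, keepdims=True)
        cond /= row_sums
        # current (k-1)-mer prefix of each sequence
        prefix = np.zeros(n, dtype=np.int64)
        for j in range(k - 1):
            prefix = prefix * 4 + out[:, p + j]
        cdf = np.cumsum(cond, axis=1)
        u = rng.random(n)
        out[:, p + k - 1] = (u[:, None] > cdf[prefix]).sum(axis=1).astype(np.uint8)
    if fell_back:
        logger.info("Markov generator fell back to marginal frequencies at "
                    "positions with unseen prefixes")
    return out


def sample_pool_from_fasta(genome: dict[str, str] | str, n: int, length: int,
                           seed: int) -> list[str]:
    """Harvest ``n`` random fixed-length regions from supplied FASTA
    sequences (fixture helper; not a genome-scale harvester).  Regions are
    drawn uniformly over all valid start positions across records."""
    from .seqmodel import read_fasta

    if not isinstance(genome, dict):
        genome = read_fasta(genome)
    rng = np.random.default_rng(seed)
    names = [k for k, v in genome.items() if len(v) >= length]
    if not names:
        raise ValueError(f"no record is at least {length} bp long")
    weights = np.array([len(genome[k]) - length + 1 for k in names], float)
    picks = rng.choice(len(names), size=n, p=weights / weights.sum())
    out = []
    for i in picks:
        seq = genome[names[i]]
        start = int(rng.integers(0, len(seq) - length + 1))
        out.append(seq[start : start + length])
    return out


def uniform_pool(n: int, length: int, seed: int,
                 gc: float | np.ndarray = 0.5) -> np.ndarray:
    """Uniform-composition random sequences (fixture helper, not genome-scale).

    ``gc`` may be a scalar or a per-sequence array of GC fractions.
    """
    rng = np.random.default_rng(seed)
    gc_arr = np.broadcast_to(np.asarray(gc, dtype=float), (n,))
    p = np.stack([(1 - gc_arr) / 2, gc_arr / 2, gc_arr / 2, (1 - gc_arr) / 2],
                 axis=1)
    cdf = np.cumsum(p, axis=1)
    u = rng.random((n, length))
    return (u[:, :, None] > cdf[:, None, :]).sum(axis=2).astype(np.uint8)
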