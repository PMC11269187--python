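"""Synthetic data with known ground truth for every analysis in the package.

The generators emulate the qualitative structure of TSS-anchored sequence
data: promoter-like windows are GC-enriched relative to a genomic-like
background pool, carry an initiator-like nucleotide bias at the initiating
base (pyrimidine at r = -1, A-enriched at r = 0), and optionally receive
planted PWM occurrences whose position determines their effect on a
per-window activity score.  Variant and MPRA generators propagate those
effects into allele-level activity differences and base-resolution
start-site count matrices.  Every generator is deterministic given a seed,
and every planted feature is recorded in a truth table so downstream
expectations never re-derive the generative math.

Default magnitudes are fixed, field-realistic choices (documented in the
methods note), not measured quantities: mammalian promoter windows average
roughly 55% GC against a genomic background near 45%, with a wide
per-region spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .seqmodel import PWM, AnchoredWindow, decode_matrix, pwm_from_consensus
from .enrichment import hit_centers

# --- study-condition defaults -------------------------------------------------
TARGET_GC_MEAN = 0.55  # promoter-like windows
TARGET_GC_SD = 0.07
POOL_GC_MEAN = 0.45  # genomic-like background pool
POOL_GC_SD = 0.12
GC_CLIP = (0.2, 0.8)
INR_MINUS1 = np.array([0.08, 0.45, 0.07, 0.40])  # pyrimidine-enriched
INR_ZERO = np.array([0.50, 0.10, 0.15, 0.25])  # A-enriched initiating base
BASELINE_ACTIVITY = 5.0
ACTIVITY_NOISE_SD = 0.5


@dataclass
class PlantSpec:
    """One motif to plant: where, how often, and what it does to activity.

    ``effect`` maps the planted center position to a log2 activity
    contribution (activator > 0, repressor < 0); ``forbid`` is an optional
    closed interval of center positions excluded from planting.
    """

    pwm: PWM
    center_range: tuple[int, int]
    prob: float
    effect: Callable[[int], float] = lambda c: 0.0
    forbid: tuple[int, int] | None = None

    def allowed_centers(self, up: int, down: int) -> np.ndarray:
        c = self.pwm.center_index
        lo = max(self.center_range[0], -up + c)
        hi = min(self.center_range[1], down - (len(self.pwm) - 1 - c))
        centers = np.arange(lo, hi + 1)
        if self.forbid is not None:
            flo, fhi = self.forbid
            centers = centers[(centers < flo) | (centers > fhi)]
        if centers.size == 0:
            raise ValueError("plant position range outside window")
        return centers


@dataclass
class SimConfig:
    """Study conditions for one simulated TSS-window dataset."""

    seed: int
    n: int = 2000
    up: int = 150
    down: int = 100
    gc_mean: float = TARGET_GC_MEAN
    gc_sd: float = TARGET_GC_SD
    inr_bias: bool = True
    plants: list[PlantSpec] = field(default_factory=list)
    baseline: float = BASELINE_ACTIVITY
    noise_sd: float = ACTIVITY_NOISE_SD

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for p in self.plants:
            if not (0.0 <= p.prob <= 1.0):
                raise ValueError("plant probability outside [0, 1]")

    @property
    def length(self) -> int:
        return self.up + self.down + 1


def _sample_biased(rng: np.random.Generator, n: int, L: int, up: int,
                   gc_mean: float, gc_sd: float, inr_bias: bool) -> np.ndarray:
    gc = np.clip(rng.normal(gc_mean, gc_sd, size=n), *GC_CLIP)
    u = rng.random((n, L))
    # cumulative base thresholds per sequence: A | C | G | T with
    # P(A) = P(T) = (1-gc)/2 and P(C) = P(G) = gc/2
    c1 = ((1 - gc) / 2)[:, None]
    c3 = ((1 + gc) / 2)[:, None]
    mat = ((u > c1).astype(np.uint8) + (u > 0.5) + (u > c3))
    if inr_bias and up >= 1:
        for col, dist in ((up - 1, INR_MINUS1), (up, INR_ZERO)):
            cdf = np.cumsum(dist)
            mat[:, col] = np.searchsorted(cdf, rng.random(n), side="right")
    return mat.astype(np.uint8)


def _sample_pwm_bases(rng: np.random.Generator, pwm: PWM, n: int) -> np.ndarray:
    cdf = np.cumsum(pwm.probs, axis=1)
    u = rng.random((n, len(pwm)))
    return (u[:, :, None] > cdf[None, :, :]).sum(axis=2).astype(np.uint8)


def simulate_tss_windows(config: SimConfig
                         ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Simulate TSS windows with planted motifs and position-dependent effects.

    Returns ``(mat, activity, truth)``: an encoded (n, L) sequence matrix,
    per-window activity scores (baseline + planted effects + Gaussian
    noise), and a truth table with one row per plant (seq_index, motif,
    center, start_col, effect).
    """
    rng = np.random.default_rng(config.seed)
    mat = _sample_biased(rng, config.n, config.length, config.up,
                         config.gc_mean, config.gc_sd, config.inr_bias)
    activity = config.baseline + rng.normal(0.0, config.noise_sd, config.n)
    truth_rows = []
    for spec in config.plants:
        centers = spec.allowed_centers(config.up, config.down)
        planted = np.where(rng.random(config.n) < spec.prob)[0]
        if planted.size == 0:
            continue
        pos = rng.choice(centers, size=planted.size)
        bases = _sample_pwm_bases(rng, spec.pwm, planted.size)
        start = pos + config.up - spec.pwm.center_index
        for i, (si, st, ce) in enumerate(zip(planted, start, pos)):
            mat[si, st : st + len(spec.pwm)] = bases[i]
            eff = float(spec.effect(int(ce)))
            activity[si] += eff
            truth_rows.append((int(si), spec.pwm.name, int(ce), int(st), eff))
    truth = pd.DataFrame(truth_rows, columns=["seq_index", "motif", "center",
                                              "start_col", "effect"])
    return mat, activity, truth


def as_windows(mat: np.ndarray, up: int, down: int,
               prefix: str = "w") -> list[AnchoredWindow]:
    """Wrap an encoded matrix as AnchoredWindow objects.  Each window is its
    own synthetic contig (chrom = window id) so that flat formats like VCF
    can address windows unambiguously."""
    seqs = decode_matrix(mat)
    return [AnchoredWindow(f"{prefix}{i}", chrom=f"{prefix}{i}", anchor=up,
                           strand="+", up=up, down=down, seq=s)
            for i, s in enumerate(seqs)]


# ---------------------------------------------------------------------------
# Variants


@dataclass
class VariantSimConfig:
    """Per-position SNV rates and how motif disruption maps to QTL slopes."""

    seed: int
    substitution_rate: float = 0.016  # per bp; ~20k SNVs over 5k x 251 bp
    effect_scale: float = 2.0  # slope units per normalized motif-score delta
    # Sampling noise of the slope estimate.  Deliberately large relative to
    # the |slope| > 0.1 inclusion threshold: association studies use lax
    # thresholds (P < 0.25) precisely because slope estimates are noisy, so
    # most retained variants are nulls.  That composition is what makes the
    # observed variant spectrum a usable null for the expected distribution.
    slope_se: float = 0.15


def simulate_variants(
    mat: np.ndarray,
    truth: pd.DataFrame,
    plants: list[PlantSpec],
    config: VariantSimConfig,
    up: int,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Scatter SNVs over windows and derive allele-level activity slopes.

    A variant falling inside a planted motif changes that motif's log-odds
    score; the allele activity difference is the plant's effect scaled by
    the normalized score change, so motif-weakening alleles lower activity
    under an activator and raise it under a repressor.  All other variants
    are nulls.  The reported slope adds Gaussian estimation noise and the
    P-value is the corresponding two-sided normal test (uniform for nulls).

    Returns (variants, activity, truth_variants): the variant table keyed by
    window index as window_id, the per-variant (slope, p) table, and the
    per-variant ground truth.
    """
    rng = np.random.default_rng(config.seed)
    n, L = mat.shape
    pwms = {p.pwm.name: p.pwm for p in plants}
    effects = {(int(r.seq_index), r.motif): (int(r.start_col), float(r.effect))
               for r in truth.itertuples(index=False)}
    plant_by_seq: dict[int, list[tuple[str, int, float]]] = {}
    for r in truth.itertuples(index=False):
        plant_by_seq.setdefault(int(r.seq_index), []).append(
            (r.motif, int(r.start_col), float(r.effect)))

    hit_mask = rng.random((n, L)) < config.substitution_rate
    si, col = np.where(hit_mask)
    keep = mat[si, col] < 4
    si, col = si[keep], col[keep]
    alt = (mat[si, col] + rng.integers(1, 4, size=si.size)) % 4

    bases = "ACGT"
    rows, act_rows, truth_rows = [], [], []
    for i, (s, cpos, a) in enumerate(zip(si, col, alt)):
        ref_b = bases[mat[s, cpos]]
        alt_b = bases[a]
        true_slope = 0.0
        in_motif = False
        for motif, start, eff in plant_by_seq.get(int(s), []):
            pwm = pwms[motif]
            if start <= cpos < start + len(pwm):
                j = cpos - start
                dscore = pwm.log_odds[j, a] - pwm.log_odds[j, mat[s, cpos]]
                true_slope += eff * dscore / (pwm.max_score / 2) \
                    * config.effect_scale
                in_motif = True
        slope = true_slope + rng.normal(0.0, config.slope_se)
        from scipy.stats import norm
        p = float(2 * norm.sf(abs(slope) / config.slope_se))
        vid = f"v{i}"
        rows.append((vid, str(int(s)), int(cpos) - up, ref_b, alt_b))
        act_rows.append((vid, slope, p))
        truth_rows.append((vid, in_motif, true_slope))
    variants = pd.DataFrame(rows, columns=["variant_id", "window_id",
                                           "rel_pos", "ref", "alt"])
    activity = pd.DataFrame(act_rows, columns=["variant_id", "slope", "p"])
    truth_v = pd.DataFrame(truth_rows, columns=["variant_id", "in_motif",
                                                "true_slope"])
    return variants, activity, truth_v


def variants_to_vcf(variants: pd.DataFrame, path, anchor: int = 150,
                    prefix: str = "w") -> None:
    """Write a minimal site-only VCF (positions 1-based, plus-strand windows).

    Each variant's CHROM is its window's contig (see :func:`as_windows`);
    numeric window ids get the same prefix.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in variants.itertuples(index=False):
            pos = anchor + int(r.rel_pos) + 1
            wid = str(r.window_id)
            chrom = wid if wid.startswith(prefix) else f"{prefix}{wid}"
            fh.write(f"{chrom}\t{pos}\t{r.variant_id}\t{r.ref}\t{r.alt}"
                     f"\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# MPRA


@dataclass
class MpraSimConfig:
    """Sequencing depth, overdispersion and barcode replication for MPRA."""

    seed: int
    depth: float = 1e4  # expected RNA reads per insert
    plasmid_mean: float = 1000.0
    n_barcodes: int = 4
    # Gamma-Poisson overdispersion; 0 = deterministic rounding.  Kept mild:
    # barcode replicates of plasmid reporter assays are highly reproducible,
    # and the planted-effect recovery checks assume near-Poisson counts.
    dispersion: float = 0.002
    length: int = 155
    tss_pos: int = 113  # inserts cover -113..+41 of the promoter
    peak_width: float = 3.0


def _base_profile(cfg: MpraSimConfig) -> np.ndarray:
    pos = np.arange(cfg.length)
    prof = np.exp(-np.abs(pos - cfg.tss_pos) / cfg.peak_width) + 0.002
    return prof / prof.sum()


def simulate_mpra(
    design: pd.DataFrame,
    effect_fn: Callable[[np.ndarray, int | None], np.ndarray],
    config: MpraSimConfig,
) -> tuple[list["InsertMatrix"], pd.DataFrame]:
    """Simulate start-site count matrices for a designed insert library.

    ``design`` has columns (insert_id, promoter, motif, planted_pos);
    ``effect_fn(positions, planted_pos)`` returns a per-position rate
    multiplier (1.0 = no effect).  Barcodes of one insert share the expected
    profile; counts are gamma-Poisson with the configured dispersion
    (dispersion 0 gives rounded expectations exactly), and plasmid counts
    are Poisson around ``plasmid_mean`` (deterministic at dispersion 0).

    Returns (inserts, truth) with truth carrying each insert's expected
    per-position rate as a list column.
    """
    from .mpra import InsertMatrix

    rng = np.random.default_rng(config.seed)
    base = _base_profile(config)
    pos = np.arange(config.length)
    inserts: list[InsertMatrix] = []
    truth_rows = []
    for r in design.itertuples(index=False):
        planted = None if pd.isna(r.planted_pos) else int(r.planted_pos)
        rate = base * effect_fn(pos, planted)
        mean = config.depth * rate
        for b in range(config.n_barcodes):
            if config.dispersion <= 0:
                counts = np.round(mean).astype(int)
                plasmid = int(round(config.plasmid_mean))
            else:
                lam = rng.gamma(shape=1.0 / config.dispersion,
                                scale=config.dispersion * np.maximum(mean, 1e-12))
                counts = rng.poisson(lam)
                plasmid = int(rng.poisson(config.plasmid_mean))
            inserts.append(InsertMatrix(
                insert_id=str(r.insert_id), promoter=str(r.promoter),
                motif=str(r.motif), planted_pos=planted,
                barcode=f"bc{b}", replicate="rep1",
                plasmid_dna_count=plasmid, start_counts=counts))
        truth_rows.append((str(r.insert_id), planted, mean.tolist()))
    truth = pd.DataFrame(truth_rows, columns=["insert_id", "planted_pos",
                                              "expected_counts"])
    return inserts, truth


def sweep_design(motif: str = "NRF1", start: int = 10, stop: int = 150,
                 step: int = 2, promoter: str = "synthP") -> pd.DataFrame:
    """Binding-site sweep design: one insert per planted position."""
    rows = [(f"{promoter}_{motif}_{p}", promoter, motif, p)
            for p in range(start, stop + 1, step)]
    return pd.DataFrame(rows, columns=["insert_id", "promoter", "motif",
                                       "planted_pos"])


# ---------------------------------------------------------------------------
# Motif-depleted synthetic promoter


def generate_motif_depleted_sequence(
    length: int,
    motif_library: Sequence[PWM],
    max_tries: int = 1000,
    seed: int | None = None,
) -> str:
    """Rejection-sample a uniform-composition sequence with zero hits to any
    library motif on either strand (a neutral scaffold for insert designs)."""
    if seed is None:
        raise ValueError("seed is mandatory")
    rng = np.random.default_rng(seed)
    for attempt in range(1, max_tries + 1):
        mat = rng.integers(0, 4, size=(1, length)).astype(np.uint8)
        clean = all(hit_centers(mat, pwm, "both").empty
                    for pwm in motif_library)
        if clean:
            seq = decode_matrix(mat)[0]
            return seq
    raise RuntimeError(
        f"no motif-free sequence found in {max_tries} tries; consider "
        "relaxing detection thresholds or shortening the sequence")


# ---------------------------------------------------------------------------
# Demo motif library and acceptance-style fixtures


def demo_motifs() -> list[PWM]:
    """A small library of consensus-derived PWMs for common promoter TFs.

    Column match probabilities vary across the motif (strong core, weaker
    flanks), as in real position weight matrices, so different mutations of
    one site produce different score changes.
    """
    return [
        pwm_from_consensus("NRF1", "GCGCATGCGC",
                           [.85, .95, .8, .97, .9, .97, .75, .95, .85, .9]),
        pwm_from_consensus("SP1", "GGGGCGGGG",
                           [.8, .95, .97, .9, .85, .97, .9, .8, .75]),
        pwm_from_consensus("NFY", "CCAATCA",
                           [.85, .95, .97, .97, .9, .8, .75]),
        pwm_from_consensus("YY1", "GCCATNTT",
                           [.8, .9, .97, .95, .9, .25, .85, .8]),
        pwm_from_consensus("TATA", "TATAWAWR",
                           [.9, .97, .95, .97, .85, .9, .8, .75]),
        pwm_from_consensus("ETS", "ACAGGAAGTG",
                           [.75, .85, .9, .97, .97, .95, .9, .85, .8, .75]),
    ]


def fixture_planted_enrichment(
    seed: int,
    n_targets: int = 2000,
    n_pool: int = 10000,
    plant_prob: float = 0.5,
    center_range: tuple[int, int] = (-60, -50),
) -> dict:
    """Targets with one PWM planted at -55 +/- 5 bp in half the windows, plus
    a motif-free genomic-like pool."""
    pwm = demo_motifs()[0]
    cfg_t = SimConfig(seed=seed, n=n_targets,
                      plants=[PlantSpec(pwm, center_range, plant_prob)])
    tmat, activity, truth = simulate_tss_windows(cfg_t)
    cfg_p = SimConfig(seed=seed + 1_000_003, n=n_pool,
                      gc_mean=POOL_GC_MEAN, gc_sd=POOL_GC_SD, inr_bias=False)
    pmat, _, _ = simulate_tss_windows(cfg_p)
    return {"tmat": tmat, "pmat": pmat, "pwm": pwm, "up": cfg_t.up,
            "activity": activity, "truth": truth}


def fixture_planted_depletion(
    seed: int,
    n_targets: int = 2000,
    n_pool: int = 10000,
    plant_prob: float = 0.3,
    forbid: tuple[int, int] = (-10, 30),
) -> dict:
    """Motif planted uniformly in both sets, but excluded from a zone of the
    targets: enrichment there should come out negative (depletion)."""
    pwm = demo_motifs()[0]
    whole = (-140, 90)
    cfg_t = SimConfig(seed=seed, n=n_targets,
                      plants=[PlantSpec(pwm, whole, plant_prob, forbid=forbid)])
    tmat, _, _ = simulate_tss_windows(cfg_t)
    cfg_p = SimConfig(seed=seed + 1_000_003, n=n_pool,
                      gc_mean=POOL_GC_MEAN, gc_sd=POOL_GC_SD, inr_bias=False,
                      plants=[PlantSpec(pwm, whole, plant_prob)])
    pmat, _, _ = simulate_tss_windows(cfg_p)
    return {"tmat": tmat, "pmat": pmat, "pwm": pwm, "up": cfg_t.up,
            "forbid": forbid}


def fixture_motif_free(seed: int, n_targets: int = 2000, n_pool: int = 10000
                       ) -> dict:
    """Type-I fixture: no planted motifs anywhere."""
    cfg_t = SimConfig(seed=seed, n=n_targets)
    tmat, _, _ = simulate_tss_windows(cfg_t)
    cfg_p = SimConfig(seed=seed + 1_000_003, n=n_pool,
                      gc_mean=POOL_GC_MEAN, gc_sd=POOL_GC_SD, inr_bias=False)
    pmat, _, _ = simulate_tss_windows(cfg_p)
    return {"tmat": tmat, "pmat": pmat, "up": cfg_t.up}


def dual_tf_effect(center: int) -> float:
    """Dual-function TF: activates at -60 +/- 10, represses at +30 +/- 10."""
    if -70 <= center <= -50:
        return 1.0
    if 20 <= center <= 40:
        return -1.0
    return 0.0


def fixture_dual_tf_variants(
    seed: int,
    n_windows: int = 5000,
    mode: str = "dual",
) -> dict:
    """Windows with a dual-function (or pure activator / pure repressor) TF
    and ~20k SNVs whose allele activity follows the effect curve."""
    pwm = demo_motifs()[0]
    if mode == "dual":
        spec = PlantSpec(pwm, (-70, 40), prob=0.8, effect=dual_tf_effect,
                         forbid=(-49, 19))
    elif mode == "activator":
        spec = PlantSpec(pwm, (-70, -50), prob=0.8, effect=lambda c: 1.0)
    elif mode == "repressor":
        spec = PlantSpec(pwm, (20, 40), prob=0.8, effect=lambda c: -1.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    cfg = SimConfig(seed=seed, n=n_windows, plants=[spec])
    mat, activity, truth = simulate_tss_windows(cfg)
    vcfg = VariantSimConfig(seed=seed + 7)
    variants, vact, vtruth = simulate_variants(mat, truth, [spec], vcfg,
                                               up=cfg.up)
    return {"mat": mat, "up": cfg.up, "pwm": pwm, "variants": variants,
            "activity": vact, "truth": truth, "variant_truth": vtruth}
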