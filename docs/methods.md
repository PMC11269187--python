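# Methods

This note documents the models and procedures implemented in `tssgrammar`,
the assumptions behind them, the tunable parameters, and the design choices
made where the method itself left room.

## Coordinates and sequence model

All positional analyses use anchor-relative, 0-based coordinates: r = 0 is
the initiating base of the TSS, r increases in the direction of
transcription, and minus-strand windows are reverse-complemented at
extraction so the rest of the stack never sees strand.  Windows default to
−150..+100 (251 bp).  Motif hits are positioned at the motif's center
column, rounded toward 5′ for even lengths, on both strands; bases marked N
score −∞ in every PWM column, so no hit can span an N.

PWMs carry per-column base probabilities (pseudocount-regularized, rows sum
to 1), a uniform-background log2-odds scoring scheme, and a detection
threshold in bits.  The bundled demo library derives PWMs from consensus
strings with per-column match probabilities that vary across the motif
(strong core, weaker flanks) — real PWMs are heterogeneous, and this matters
downstream: with identical columns every mutation of a site would produce
the same score change and the saturation-mutagenesis null would collapse to
two atoms.

## Matched background selection

The central confounder of TSS-anchored motif enrichment is that promoter
windows differ from genomic background both in overall GC and in
position-dependent nucleotide composition.  Background selection therefore
proceeds in two stages inside GC bins:

1. **GC binning.**  Targets are split into `n_bins` (default 10)
   equal-count bins by per-sequence GC (quantile edges; ties broken by
   stable input order); pool candidates are assigned to the same edges.
   Bins short of candidates borrow nearest-GC neighbours with a warning.
2. **Iterative descent.**  Within each bin, candidates are progressively
   removed: each iteration computes the per-position k-mer frequency
   difference (target − background; k = 2 by default), scores every
   sequence by the summed differences of the k-mers it contains, and
   resamples the retained set so its score distribution tracks the
   targets'.  The retention weights are the importance ratio of
   kernel-smoothed histogram densities (Gaussian kernel, Silverman
   bandwidth) of the target and current-background score distributions —
   weighting by the target density alone would converge to the product of
   the two densities rather than the target distribution.
3. **Exchange polish.**  Once the requested size is reached, a global
   exchange stage swaps selected/reserve sequences within bins while the
   swap reduces the total L1 frequency difference.  Because a swap at fixed
   size changes each position's k-mer counts by exactly ±1, the L1 gain of
   a single swap is exact and cheap: adding a count at a coordinate with
   frequency difference d is worth |d| − |d − 1/n| and removing one
   |d| − |d + 1/n|.  Greedy batched swaps run to a single-swap local
   optimum; the additive two-sequence estimate is a lower bound on the
   exact pair gain (shared k-mers cancel instead of paying both
   penalties), so a few rounds of exact pair evaluation over the top
   candidates follow.  The convergence trace reports the best L1 so far.

Defaults: `n_select` = 2 × targets (suited to genome-scale pools; with
desk-scale pools of ~5 × the target count an equal-size background leaves
more selection freedom and is what the bundled end-to-end checks use),
`max_iter` 100, removal factor 0.9 per iteration, tolerance 0.01 ×
window length, 300 polish passes.  A seed is mandatory; selection is
deterministic given inputs and seed.

What selection can and cannot match: subsampling can reproduce any
*compositional* property present in the pool at sufficient frequency, but
it cannot conjure strong position-specific features that the pool lacks.
In particular, planted motifs (~5× dimer over-representation at ~13
specific positions) and initiator bases leave a small irreducible residual;
this is by design — composition matching must *not* replicate motifs, or
enrichment would be blind.

The position-dependent Markov generator offers a fully synthetic
alternative: the initial k-mer is drawn from the position-0 k-mer
distribution and each next base from the conditional of the next position's
k-mer distribution given its (k−1)-prefix, falling back to the positional
marginal for unseen prefixes.

## Windowed enrichment

Target and matched-background sequences are scanned per motif and strand;
per grid window (starts every `step` bp from the range start through its
end, width `width`, clipped at the range end — 26 windows for
−150..+100/30/10) a 2×2 table counts *sequences* with at least one hit
center in the window.  Sequence-level counting is used because occurrence
counts violate the independence assumption of the Fisher exact test;
occurrence-level counting is retained for density histograms (motifs per bp
per TSS).  The one-sided hypergeometric tail is taken in the direction of
the observed effect and signed: signed_logP = ±log10(P_adj), positive for
enrichment.  BH correction spans all (motif, strand, window) cells of one
invocation.  P-values are floored at 1e−300 before logs.

## Positional analytics

- **Power spectrum:** densities over −120..−40 bp are mean-subtracted and
  the Fourier power |Σ d(x)·e^(−2πi·x/T)|² is evaluated directly on the
  period grid 0.1–50 bp (0.1 bp steps; T = 0 is undefined and excluded),
  then normalized to a maximum of 1.  Constant densities yield a flagged
  all-zero spectrum.
- **Partial-correlation profiles:** at each position the motif is placed
  with its center there; per sequence the log2-odds (−∞ clamped to the
  finite dataset minimum — raw clamped scores, not zeroed, so weak sites
  retain information), the sequence score, and the GC fraction enter the
  first-order partial correlation r_xy·z.  Zero-variance positions are
  flagged and reported as 0.
- **TF–TF spacing:** non-redundant A-motif sites (greedy by descending
  score, exclusion radius one motif length) anchor rows; every B hit within
  ±300 bp contributes one row (regions with several B hits appear once per
  hit), rows sorted by B−A offset, with initiation signal re-centered on A.
- **Initiator stratification:** the hexamer at r = −3..+2 is matched
  against BBCA+1BW with the A at r = 0; any N is a non-call.  Exactly 54 of
  the 4,096 hexamers match.

## Variant association

Variants are SNVs near TSSs (≤ 200 bp by default), oriented so the allele
associated with higher activity is "active" (tssQTL mode: |slope| > 0.1 and
P < 0.25, active = alt for positive slopes; strain mode: external
differential calls).  For a motif and distance window, the observed
distribution collects score deltas (active − inactive) at the best-scoring
motif placement overlapping the variant in either allele, with the center
inside the window.  The expected distribution is a saturation-mutagenesis
scan — every (sequence, position, substitution) delta with an
above-threshold placement in either allele — weighted so each substitution
class (position, inactive base → active base) carries total weight equal to
its observed count, split equally among contributing sequences.  Classes
are counted in active-orientation so expected and observed live on the same
scale.  This is equivalent to randomizing the sequence context of each
observed variant while preserving its position and nucleotide identity.

The comparison uses a weighted Mann–Whitney U: U accumulates expected
weights below each observation (half-weight ties).  Treating each weighted
value as an independent fractional pseudo-observation, the exact null
variance is

    Var(U) = n₁/12 · (W² + (n₁+1)·Σw²) · (1 − tie factor),

with W = Σw and the tie factor computed on pooled weights.  At unit weights
this is exactly the tie-corrected classical MWU variance; with many small
weights it approaches the fixed-distribution limit n₁W²(1−Σp³)/12, which is
what keeps P-values uniform when observations really are draws from the
expected distribution.  A 0.5 continuity correction matches the classical
convention.  Windows with fewer than `min_obs` (default 10) observed deltas
are not tested; BH spans all tested cells; positive sign = observed deltas
stochastically larger = activator-like.

A note on the method's operating regime: the expected distribution's class
weights come from *all* retained variants at a position, most of which do
not touch the tested motif.  Association studies use deliberately lax
inclusion thresholds (P < 0.25) because slope estimates are noisy, so the
retained set is dominated by null variants and the class weights reflect
the position's variant spectrum rather than the tested motif's own effect.
The synthetic generator reproduces this regime (slope standard error 0.15
against the 0.1 threshold); with nearly noiseless slopes the retained
variants at causal positions would be mostly causal, the expected
distribution would absorb the signal, and sensitivity would collapse —
a property of the method, not of the implementation.

## TSS calling

5′-end counts are normalized to reads per 10⁷ aligned reads.  A position is
confident when its pooled normalized count across all compared samples
reaches 7 per 10⁷ (a per-sample-minimum mode is available, since "across
all compared replicates" is ambiguous); positions with strictly higher
normalized density in the small-RNA input track are discarded (ties kept).
TSRs form by greedy single-linkage of same-strand TSSs within `max_gap`
(default 150 bp — a package choice, configurable).  Differential activity
statistics are consumed from external tables, never computed here.

## MPRA quantification

Start-site counts are scaled by min(10000/plasmid, 100); inserts with fewer
than 50 plasmid DNA alignments are unusable and reported.  A pseudocount of
1 precedes the log2; barcode/technical replicates merge by averaging.
Sweep profiles subtract the position-wise mean reference coverage, re-index
by distance to the planted motif and average; LOESS smoothing (span 0.1,
tricube weights, degree 2 — written in-package because available smoothers
are locally linear) applies to the visual track only.  Insertion effects
are log2 ratios of scaled (unlogged) counts summed over ±7 bp around the
designated TSS, inclusive at both ends (15 positions), barcodes averaged
before the ratio (per-barcode ratios available).  TSS shifts subtract
weighted-mean positions (weights = scaled counts).  Mutated sites are
labeled enriched-/depleted-position by the sign of significant covering
cells (P_adj < 0.01) of a genomic-context enrichment map; motifs with fewer
than 20 distinct promoters are excluded from summaries.

## Synthetic data: what it does and does not emulate

Generators are seeded and bit-reproducible; every planted feature lands in
a truth table so downstream expectations never re-derive generative math.

- **Windows:** per-sequence GC ~ Normal(0.55, 0.07) for promoter-like
  targets and Normal(0.45, 0.12) for genomic-like pools (clipped to
  [0.2, 0.8]) — realistic means for mammalian promoters vs. genome; an
  initiator-like bias puts pyrimidines at r = −1 and A-enrichment at r = 0.
  Plants overwrite bases sampled from the PWM (so a realistic fraction of
  sites is weak); activity = baseline + position-dependent effects +
  Gaussian noise (sd 0.5).
- **Variants:** SNVs scatter uniformly (default 0.016/bp ≈ 20k over 5k
  windows); a variant inside a planted motif shifts activity by the effect
  times the normalized score change, and the reported slope adds Gaussian
  estimation noise (se 0.15; see above) with the matching two-sided normal
  P-value.
- **MPRA:** expected start-site profiles are exponential peaks at the
  designated TSS scaled by per-position effect multipliers; counts are
  gamma-Poisson with mild overdispersion (0.002 — reporter barcode
  replicates are highly reproducible; dispersion 0 gives rounded
  expectations exactly), plasmid counts Poisson around 1,000, 4 barcodes
  per insert.

Not emulated: chromatin context, Pol II kinetics, mappability artifacts,
linked variants/haplotypes, indels, cross-position GC autocorrelation
within single sequences beyond the per-sequence GC draw.  Passing the
bundled end-to-end checks therefore demonstrates correct and calibrated
machinery on data satisfying these assumptions, not performance on any
particular real dataset.

## Numerical choices and known limitations

- Fisher tails come from scipy's hypergeometric distribution (verified to
  1e−12 against exact rational tail sums); BH uses the standard step-up.
- Impossible placements in the variant machinery use a −10⁴ sentinel (far
  below any threshold) instead of −∞ so allele deltas stay finite.
- The exchange descent leaves the background's positional dinucleotide L1
  distance to the targets typically well below the two-sample iid noise
  floor, but structural residuals remain at planted-motif and initiator
  coordinates (see above); on desk-scale fixtures the matched distance is
  roughly 22% of an unmatched random draw's (dominated by that structural
  floor), improving with pool size.
- The weighted MWU's P is not exactly invariant to splitting expected
  weights across duplicated support values: a finer-grained support
  genuinely carries more information (U and the sign are exactly
  invariant).
- `classify_tss_annotation` applies precedence promoter >
  promoter-antisense > distal > other when classes overlap.
- Grid windows at the range end are clipped, so trailing windows can be
  narrower than `width`.
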