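# tssgrammar

Position-aware transcription-factor (TF) motif analysis anchored at
transcription start sites (TSSs).

Regulatory elements carry similar assortments of TF binding sites, yet
drive very different transcription programs.  A large part of the missing
information is *positional*: where a binding site sits relative to the
initiating base determines whether the factor activates or represses
initiation.  Measuring this is statistically treacherous, because the
sequence immediately around TSSs has strong position-dependent nucleotide
biases (initiator elements, GC-rich cores) that confound naive motif
enrichment.  `tssgrammar` implements the analysis stack needed to do this
properly on TSS-anchored data:

- **Matched backgrounds** (`tssgrammar.background`): select background
  sequences from a candidate pool so that both the per-sequence GC
  distribution (quantile bins, default 10) and the per-position k-mer
  frequencies (default k = 2, dinucleotides) match the targets.  Selection
  is an iterative descent that progressively removes candidates, followed
  by an exact-gain exchange stage; a position-dependent Markov generator
  can synthesize backgrounds instead.
- **Positional enrichment maps** (`tssgrammar.enrichment`): PWM log2-odds
  scanning (hits placed at the motif center), one-sided Fisher exact tests
  per window of a start/width/step grid (e.g. 30 bp windows every 10 bp
  over −150..+100), Benjamini–Hochberg correction across the whole map, and
  signed log10 adjusted P-values (positive = enriched, negative = depleted).
- **Positional analytics** (`tssgrammar.profiles`): Fourier power spectra
  of binding-site density over −120..−40 bp (periods 0.1–50 bp in 0.1 bp
  steps, helical periodicity), per-position partial Pearson correlation of
  motif score with sequence activity controlling for GC content, initiator
  (BBCA+1BW) stratification, and TF–TF spacing matrices.
- **Natural genetic variation** (`tssgrammar.genvar`): orient alleles by
  activity (tssQTL slopes, |slope| > 0.1 and P < 0.25, or strain
  differentials), compute motif log-odds changes (active − inactive) for
  variants in binding sites, and test them per distance window against a
  saturation-mutagenesis expected distribution — every possible
  substitution of every sequence, weighted by the observed variant spectrum
  at each position — using a weighted Mann–Whitney U test.  Positive signed
  log P: activator-like; negative: repressor-like.
- **TSS calling** (`tssgrammar.tsscall`): single-base TSS filters for
  capped-small-RNA 5′-end counts (≥ 7 reads per 10⁷ pooled across compared
  samples; discard positions with higher normalized input density) and TSR
  grouping.
- **TSS-MPRA quantification** (`tssgrammar.mpra`): scale start-site counts
  by min(10000/plasmid, 100) (inserts with < 50 plasmid reads are
  unusable), log2(x+1), average barcodes, then compute binding-site sweep
  profiles, ±7 bp insertion effects, and weighted-mean TSS shifts.
- **Synthetic data** (`tssgrammar.synth`): seeded generators for
  promoter-like windows with planted motifs and position-dependent effect
  curves, SNVs with allele-level activity, and MPRA count matrices — every
  planted feature recorded in a truth table.

## Worked example

Recover a planted positional signal end to end:

```python
import tssgrammar as tg
from tssgrammar import synth

# 2,000 promoter-like windows (-150..+100), NRF1 planted at -55 +/- 5 bp in
# half of them; 10,000 genomic-like pool sequences
fx = synth.fixture_planted_enrichment(seed=7)
emap, diag = tg.enrichment_with_matched_background(
    fx["tmat"], fx["pmat"], [fx["pwm"]],
    seed=7, up=fx["up"], n_select=2000)

print("strongest window:", emap.global_max_window())
print(emap.table.nlargest(2, "signed_logP")[
    ["window_start", "window_end", "target_count", "background_count",
     "signed_logP"]])
```

```
strongest window: (-70, -41)
   window_start  window_end  target_count  background_count  signed_logP
8           -70         -41           694                 1   236.696293
9           -60         -31           694                 3   232.525618
```

694 of 2,000 target windows carry a detectable site in the −70..−41 window
against 1 of 2,000 in the dinucleotide-matched background, giving a signed
log10 adjusted P of +237 — the planted position is recovered exactly.
(Plants are sampled from the PWM, so roughly 60% of the 1,000 planted
windows carry a site above the detection threshold.)

The same fixtures drive the variant analysis:

```python
fx = synth.fixture_dual_tf_variants(seed=3, mode="dual")
oriented, _ = tg.assign_orientation(fx["variants"], fx["activity"])
table = tg.positional_association_test(oriented, fx["mat"], fx["pwm"],
                                       up=fx["up"])
print(table.loc[table["p_adj"] < 0.01,
                ["window_start", "window_end", "signed_logP"]])
```

```
    window_start  window_end  signed_logP
6            -90         -61    33.724335
7            -80         -51    84.787318
8            -70         -41    94.790620
9            -60         -31    33.084321
15             0          29    -3.086906
16            10          39    -3.626113
17            20          49    -3.578329
18            30          59    -6.381592
19            40          69    -2.747704
```

The dual-function factor comes out strongly positive (activating) around
−60 and negative (repressing) around +30, matching the simulated truth.

A command-line interface (`tssgrammar windows|background|enrich|spectrum|
mepp|spacing|genvar|calltss|tsr|simulate|mpra`) wraps the same functions
for FASTA/BED/TSV inputs; a small demo motif library ships at
`src/tssgrammar/data/known.motifs`.

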