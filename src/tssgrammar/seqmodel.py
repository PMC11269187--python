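"""Core domain types and I/O for TSS-anchored sequence analysis.

Coordinate convention used throughout the package: positions are expressed
relative to the anchor (the initiating base of a transcription start site),
0-based, with r = 0 being the initiating base itself.  Biological "+1"
notation therefore maps to r = 0.  Windows are transcription-oriented: for
minus-strand anchors the genomic span is reverse-complemented so that r
increases in the direction of transcription.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("tssgrammar")

# ---------------------------------------------------------------------------
# Alphabet helpers

BASES = "ACGT"
_BASE_TO_INT = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_INT_TO_BASE = np.array(list("ACGTN"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC code -> set of matching bases
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 (A=0, C=1, G=2, T=3, N=4)."""
    out = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    table = np.full(128, 4, dtype=np.uint8)
    for b, i in _BASE_TO_INT.items():
        table[ord(b)] = i
    return table[out]


def encode_matrix(seqs: Sequence[str]) -> np.ndarray:
    """Encode equal-length sequences as an (n, L) uint8 matrix."""
    if not seqs:
        return np.zeros((0, 0), dtype=np.uint8)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have mixed lengths: {sorted(lengths)}")
    joined = "".join(seqs)
    return encode(joined).reshape(len(seqs), -1)


def decode_matrix(mat: np.ndarray) -> list[str]:
    """Inverse of :func:`encode_matrix`."""
    return ["".join(row) for row in _INT_TO_BASE[mat]]


def gc_fraction(seq: str | np.ndarray) -> float:
    """GC fraction of a sequence; N bases are excluded from the denominator."""
    enc = encode(seq) if isinstance(seq, str) else seq
    valid = enc < 4
    n = int(valid.sum())
    if n == 0:
        return np.nan
    return float(((enc == 1) | (enc == 2)).sum() / n)


def gc_fraction_matrix(mat: np.ndarray) -> np.ndarray:
    """Per-row GC fraction of an encoded matrix (Ns excluded)."""
    valid = (mat < 4).sum(axis=1)
    gc = ((mat == 1) | (mat == 2)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(valid > 0, gc / np.maximum(valid, 1), np.nan)


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class AnchoredWindow:
    """A fixed-length, transcription-oriented window around one TSS.

    ``seq`` covers relative coordinates r in [-up, +down]; r = 0 is the
    initiating base.  For minus-strand anchors ``seq`` is the reverse
    complement of the genomic span, so r always increases in the direction
    of transcription.
    """

    window_id: str
    chrom: str
    anchor: int  # 0-based genomic position of the TSS base
    strand: str  # '+' or '-'
    up: int
    down: int
    seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if len(self.seq) != self.up + self.down + 1:
            raise ValueError(
                f"window {self.window_id}: sequence length {len(self.seq)} "
                f"!= up+down+1 = {self.up + self.down + 1}"
            )
        bad = set(self.seq.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"window {self.window_id}: invalid bases {bad}")
        self.seq = self.seq.upper()

    def base_at(self, r: int) -> str:
        """Base at relative coordinate r (r = 0 is the initiating base)."""
        if not (-self.up <= r <= self.down):
            raise IndexError(f"r={r} outside [-{self.up}, {self.down}]")
        return self.seq[r + self.up]

    def slice_rel(self, r_start: int, r_end: int) -> str:
        """Subsequence covering relative coordinates [r_start, r_end]."""
        return self.seq[r_start + self.up : r_end + self.up + 1]


@dataclass
class PWM:
    """A named position probability matrix scored as log2-odds.

    ``probs`` has one row per motif column and 4 columns (A, C, G, T).
    ``detection_threshold`` is in log2-odds bits against ``background``.
    """

    name: str
    consensus: str
    probs: np.ndarray
    detection_threshold: float
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError(f"motif {self.name}: probs must be L x 4")
        if len(self) < 4:
            raise ValueError(f"motif {self.name}: length {len(self)} < 4")
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"motif {self.name}: columns do not sum to 1")
        if (self.probs <= 0).any():
            raise ValueError(f"motif {self.name}: non-positive probabilities")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def center_index(self) -> int:
        """Index of the motif's center column, rounded toward 5' for even lengths."""
        return (len(self) - 1) // 2

    @property
    def log_odds(self) -> np.ndarray:
        """(L, 4) log2-odds score matrix against the background frequencies."""
        return np.log2(self.probs / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        """PWM scoring the reverse-complement orientation of this motif."""
        return PWM(
            name=self.name,
            consensus=revcomp(self.consensus.translate(_rc_iupac())),
            probs=self.probs[::-1, ::-1].copy(),
            detection_threshold=self.detection_threshold,
            background=self.background[::-1].copy(),
        )


def _rc_iupac():
    return str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass
class MotifHit:
    """One above-threshold PWM match, positioned at the motif's center."""

    motif: str
    window_id: str
    rel_pos: int  # motif center, relative to the anchor
    strand_of_hit: str  # 'sense' or 'antisense'
    score: float


@dataclass
class GeneAnnotation:
    """Annotated gene TSS positions (chrom, position, strand)."""

    table: pd.DataFrame  # columns: chrom, pos, strand

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "strand"}
        if not required <= set(self.table.columns):
            raise ValueError(f"annotation needs columns {sorted(required)}")
        if (self.table["pos"] < 0).any():
            raise ValueError("annotation contains negative positions")
        if not self.table["strand"].isin(["+", "-"]).all():
            raise ValueError("annotation contains invalid strands")

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# FASTA / BED / TSV I/O


def read_bed6(path: str | Path) -> pd.DataFrame:
    """Read a BED6 file (0-based half-open; strand required).

    thickStart/thickEnd and further columns, if present, are ignored.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype={0: str}
    ).iloc[:, :6]
    df.columns = ["chrom", "start", "end", "name", "score", "strand"]
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("BED6 input requires '+'/'-' in the strand column")
    return df


def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (small) multi-record FASTA into an ordered dict of sequences."""
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.upper())
    if name is not None:
        records[name] = "".join(chunks)
    return records


def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]],
                path: str | Path, width: int = 80) -> None:
    items = records.items() if isinstance(records, dict) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def windows_to_fasta(windows: Sequence[AnchoredWindow], path: str | Path) -> None:
    write_fasta(((w.window_id, w.seq) for w in windows), path)


def windows_from_fasta(path: str | Path, up: int, down: int) -> list[AnchoredWindow]:
    """Re-read windows written by :func:`windows_to_fasta` (anchor metadata lost)."""
    out = []
    for name, seq in read_fasta(path).items():
        out.append(AnchoredWindow(name, chrom=".", anchor=0, strand="+",
                                  up=up, down=down, seq=seq))
    return out


# ---------------------------------------------------------------------------
# Window extraction


def extract_anchored_windows(
    genome: str | Path | dict[str, str],
    anchors: str | Path | pd.DataFrame,
    up: int,
    down: int,
) -> list[AnchoredWindow]:
    """Cut transcription-oriented windows around BED6 anchors.

    The anchor base is the BED interval's start for '+' entries and end-1
    for '-' entries.  Windows overrunning a contig end are dropped with a
    warning; an anchor on a chromosome absent from the genome is a hard
    error.

    ``genome`` may be a FASTA path (read via pyfaidx for random access) or a
    dict of sequences.
    """
    if up < 0 or down < 0:
        raise ValueError("up and down must be >= 0")
    if isinstance(anchors, (str, Path)):
        anchors = read_bed6(anchors)

    if isinstance(genome, dict):
        get_len = lambda c: len(genome[c])  # noqa: E731
        fetch = lambda c, s, e: genome[c][s:e]  # noqa: E731
        has = lambda c: c in genome  # noqa: E731
    else:
        import pyfaidx

        fa = pyfaidx.Fasta(str(genome))
        get_len = lambda c: len(fa[c])  # noqa: E731
        fetch = lambda c, s, e: str(fa[c][s:e]).upper()  # noqa: E731
        has = lambda c: c in fa  # noqa: E731

    windows: list[AnchoredWindow] = []
    dropped = 0
    for row in anchors.itertuples(index=False):
        chrom, strand = row.chrom, row.strand
        if not has(chrom):
            raise KeyError(f"anchor chromosome {chrom!r} absent from genome FASTA")
        anchor = int(row.start) if strand == "+" else int(row.end) - 1
        if strand == "+":
            g_start, g_end = anchor - up, anchor + down + 1
        else:
            g_start, g_end = anchor - down, anchor + up + 1
        if g_start < 0 or g_end > get_len(chrom):
            dropped += 1
            logger.warning(
                "window %s overruns contig %s bounds; dropped", row.name, chrom
            )
            continue
        seq = fetch(chrom, g_start, g_end)
        if strand == "-":
            seq = revcomp(seq)
        windows.append(
            AnchoredWindow(str(row.name), chrom, anchor, strand, up, down, seq)
        )
    if dropped:
        logger.warning("dropped %d window(s) overrunning contig ends", dropped)
    return windows


# ---------------------------------------------------------------------------
# Motif library I/O (HOMER-style text dialect)


def read_motif_library(path: str | Path, pseudocount: float = 1e-3) -> list[PWM]:
    """Parse a motif text file: '>name<TAB>consensus<TAB>threshold' headers
    followed by rows of 4 tab-separated base probabilities (A C G T).

    Zero probabilities are replaced by ``pseudocount`` and each row is
    renormalized.  A row whose probabilities do not sum to 1 within 0.01
    before renormalization is an error naming the motif and column.
    """
    pwms: list[PWM] = []
    header: list[str] | None = None
    rows: list[list[float]] = []

    def _flush():
        nonlocal header, rows
        if header is None:
            return
        if not rows:
            raise ValueError(f"motif {header[0]}: no probability rows")
        probs = np.array(rows, dtype=float)
        sums = probs.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > 0.01)[0]
        if bad.size:
            raise ValueError(
                f"motif {header[0]}: column {bad[0] + 1} probabilities sum to "
                f"{sums[bad[0]]:.4f}, not 1 within 0.01"
            )
        probs = np.maximum(probs, pseudocount)
        probs /= probs.sum(axis=1, keepdims=True)
        pwms.append(
            PWM(
                name=header[0],
                consensus=header[1],
                probs=probs,
                detection_threshold=float(header[2]),
            )
        )
        header, rows = None, []

    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                _flush()
                parts = line[1:].split("\t")
                if len(parts) < 3:
                    raise ValueError(
                        f"line {ln}: motif header needs name, consensus, threshold"
                    )
                header = parts[:3]
            else:
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise ValueError(f"line {ln}: expected 4 probabilities")
                rows.append(vals)
    _flush()
    if not pwms:
        raise ValueError(f"motif file {path} contains no motifs")
    return pwms


def write_motif_library(pwms: Sequence[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\t{pwm.consensus}\t{pwm.detection_threshold:g}\n")
            for row in pwm.probs:
                fh.write("\t".join(f"{p:.6f}" for p in row) + "\n")


def pwm_from_consensus(
    name: str,
    consensus: str,
    match_prob: float | Sequence[float] = 0.95,
    threshold_fraction: float = 0.75,
    background: np.ndarray | None = None,
) -> PWM:
    """Build a PWM from an IUPAC consensus.

    ``match_prob`` (scalar or per-column) is split among the allowed bases,
    the remainder among the others; real motifs have columns of varying
    information content, so per-column probabilities are recommended.  The
    detection threshold is ``threshold_fraction`` of the maximum log2-odds
    score.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    mp = np.broadcast_to(np.asarray(match_prob, dtype=float),
                         (len(consensus),))
    rows = []
    for ch, m in zip(consensus.upper(), mp):
        allowed = [(("ACGT").index(b)) for b in IUPAC[ch]]
        row = np.full(4, (1 - m) / max(4 - len(allowed), 1))
        row[allowed] = m / len(allowed)
        if len(allowed) == 4:
            row = np.full(4, 0.25)
        rows.append(row / row.sum())
    probs = np.array(rows)
    pwm = PWM(name, consensus, probs, 0.0, bg)
    pwm.detection_threshold = threshold_fraction * pwm.max_score
    return pwm


# ---------------------------------------------------------------------------
# Initiator classification


def classify_inr(window: AnchoredWindow) -> bool:
    """True iff r = -3..+2 matches the initiator element BBCA+1BW with the
    A at r = 0 (B = C/G/T, W = A/T).  Any N in the hexamer is a non-call."""
    if window.up < 3 or window.down < 2:
        raise ValueError("window must cover relative positions -3..+2")
    hexamer = window.slice_rel(-3, 2)
    if "N" in hexamer:
        logger.debug("window %s: N in initiator hexamer", window.window_id)
        return False
    pattern = "BBCABW"
    return all(base in IUPAC[code] for base, code in zip(hexamer, pattern))


def classify_tss_annotation(
    tss: tuple[str, int, str],
    annotation: GeneAnnotation,
    promoter_dist: int = 200,
    antisense_range: tuple[int, int] = (-400, 200),
    distal_min: int = 1000,
) -> str:
    """Classify a TSS against annotated gene TSSs.

    promoter: same strand and within ``promoter_dist`` of an annotated TSS;
    promoter_antisense: opposite strand with the signed distance (measured
    in the annotated TSS's orientation) within ``antisense_range``;
    distal: more than ``distal_min`` bp from every annotated TSS;
    other: anything else.
    """
    chrom, pos, strand = tss
    ann = annotation.table
    ann = ann[ann["chrom"] == chrom]
    if ann.empty:
        logger.warning("empty annotation for %s; classifying as distal", chrom)
        return "distal"
    orient = np.where(ann["strand"] == "+", 1, -1)
    d = (pos - ann["pos"].to_numpy()) * orient  # in annotated-TSS orientation
    same = (ann["strand"] == strand).to_numpy()
    if (same & (np.abs(d) <= promoter_dist)).any():
        return "promoter"
    lo, hi = antisense_range
    if ((~same) & (d >= lo) & (d <= hi)).any():
        return "promoter_antisense"
    if np.abs(pos - ann["pos"].to_numpy()).min() > distal_min:
        return "distal"
    return "other"
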