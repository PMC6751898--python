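"""Motif matrices, genomic windows, and PWM binding-affinity scanning.

The affinity of a motif for a region is the sum, over every window on both
strands, of the product of position probabilities (REDUCE-family occupancy
score).  It is non-negative, grows with sequence length, and serves as the
design matrix for the activity regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# degenerate/unknown bases map to code 4 (scored zero)
_ENCODE = np.full(256, 4, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_RC_CODE = np.array([3, 2, 1, 0, 4], dtype=np.int8)

#: window geometry used throughout: 300 bp upstream / 100 bp downstream of the
#: dominant TSS peak for promoters; +/-200 bp of the midpoint for enhancers.
PROMOTER_UPSTREAM = 300
PROMOTER_DOWNSTREAM = 100
ENHANCER_FLANK = 200


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a DNA string to integer codes A=0, C=1, G=2, T=3, other=4."""
    return _ENCODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def reverse_complement(sequence: str) -> str:
    comp = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")
    return sequence.translate(comp)[::-1]


@dataclass(frozen=True)
class MotifMatrix:
    """A position probability matrix (rows A, C, G, T) with identity metadata."""

    motif_id: str
    tf_name: str
    probabilities: np.ndarray  # shape (4, w)
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or p.shape[0] != 4:
            raise ValueError(f"motif {self.motif_id}: matrix must be 4 x w")
        w = p.shape[1]
        if not 1 <= w <= 30:
            raise ValueError(f"motif {self.motif_id}: width {w} outside [1, 30]")
        sums = p.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"motif {self.motif_id}: columns must sum to 1")
        object.__setattr__(self, "probabilities", p)

    @property
    def width(self) -> int:
        return self.probabilities.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probabilities.argmax(axis=0))


def read_jaspar(path: str | Path, pseudocount: float = 1.0) -> list[MotifMatrix]:
    """Parse motifs from JASPAR PFM text (``>ID name`` + 4 count rows).

    Counts are incremented by ``pseudocount`` and normalised to
    column-stochastic probabilities.  A zero count with ``pseudocount=0`` is
    rejected: every probability must be strictly positive.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    text = Path(path).read_text()
    motifs: list[MotifMatrix] = []
    header: str | None = None
    rows: list[np.ndarray] = []

    def flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        if len(rows) != 4:
            raise ValueError(f"motif record '{header}' has {len(rows)} rows, expected 4")
        counts = np.vstack(rows)
        if (counts < 0).any():
            raise ValueError(f"motif record '{header}' has negative counts")
        counts = counts + pseudocount
        if (counts <= 0).any():
            raise ValueError(
                f"motif record '{header}': zero probability forbidden; "
                "use a positive pseudocount"
            )
        parts = header.split(None, 1)
        motif_id = parts[0]
        tf_name = parts[1].strip() if len(parts) > 1 else motif_id
        probs = counts / counts.sum(axis=0, keepdims=True)
        motifs.append(MotifMatrix(motif_id, tf_name, probs, pseudocount))
        header, rows = None, []

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
        else:
            # rows look like "A  [ 0 3 79 ... ]" or bare numbers
            body = line
            if body[0].upper() in BASES and not body[0].isdigit():
                body = body[1:]
            body = body.replace("[", " ").replace("]", " ")
            rows.append(np.array([float(x) for x in body.split()], dtype=float))
    flush()
    if not motifs:
        raise ValueError(f"no motif records found in {path}")
    widths = {m.width for m in motifs}
    if any(w < 1 for w in widths):
        raise ValueError("empty motif encountered")
    return motifs


def write_jaspar(motifs: Iterable[MotifMatrix], path: str | Path, scale: float = 100.0) -> None:
    """Write motifs as JASPAR PFM text, probabilities scaled to pseudo-counts."""
    lines: list[str] = []
    for m in motifs:
        lines.append(f">{m.motif_id} {m.tf_name}")
        for i, base in enumerate(BASES):
            vals = " ".join(f"{v * scale:.10f}" for v in m.probabilities[i])
            lines.append(f"{base} [ {vals} ]")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval tagged with its region class."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "promoter"
    region_id: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def promoter_window(
    peak_pos: int,
    strand: str,
    chrom_length: int,
    chrom: str = "",
    region_id: str = "",
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> GenomicInterval:
    """Window of ``upstream`` bp before and ``downstream`` bp after the
    dominant peak, on the promoter's strand.

    Upstream/downstream are strand-relative: on ``-`` the window mirrors to
    ``[peak - downstream, peak + upstream)``.  Windows that would overrun a
    chromosome edge are errors, never clipped, so that all rows of the design
    matrix score sequences of equal length.
    """
    if not 0 <= peak_pos < chrom_length:
        raise ValueError(f"peak {peak_pos} outside chromosome of length {chrom_length}")
    if strand == "+":
        start, end = peak_pos - upstream, peak_pos + downstream
    elif strand == "-":
        start, end = peak_pos - downstream, peak_pos + upstream
    else:
        raise ValueError(f"strand must be + or -, got {strand!r}")
    if start < 0 or end > chrom_length:
        raise ValueError(
            f"promoter window [{start}, {end}) for {region_id or 'peak'} at {peak_pos} "
            "overruns the chromosome; windows are not clipped"
        )
    return GenomicInterval(chrom, start, end, strand, "promoter", region_id)


def enhancer_window(
    midpoint: int,
    chrom_length: int,
    chrom: str = "",
    region_id: str = "",
    flank: int = ENHANCER_FLANK,
) -> GenomicInterval:
    """Strand-agnostic window of ``flank`` bp either side of the midpoint."""
    if not 0 <= midpoint < chrom_length:
        raise ValueError(f"midpoint {midpoint} outside chromosome of length {chrom_length}")
    start, end = midpoint - flank, midpoint + flank
    if start < 0 or end > chrom_length:
        raise ValueError(
            f"enhancer window [{start}, {end}) for {region_id or 'midpoint'} at "
            f"{midpoint} overruns the chromosome"
        )
    return GenomicInterval(chrom, start, end, "+", "enhancer", region_id)


def select_dominant_peak(position_expression: Mapping[int, float], strand: str = "+") -> int:
    """Position with the highest summed expression; ties go to the 5'-most
    position on the promoter's strand (smallest coordinate on ``+``, largest
    on ``-``)."""
    if not position_expression:
        raise ValueError("promoter has no expressed positions")
    total = sum(position_expression.values())
    if total <= 0:
        raise ValueError("promoter has zero expression at every position")
    best = max(position_expression.values())
    tied = [pos for pos, v in position_expression.items() if v == best]
    return min(tied) if strand == "+" else max(tied)


def extract_sequences(
    fasta_path: str | Path, intervals: Sequence[GenomicInterval]
) -> dict[str, str]:
    """Uppercase forward-genome-strand sequence for each interval.

    Scanning is double-stranded downstream, so no reverse-complementing
    happens here; ``N`` bases are retained and zeroed during scoring.
    """
    from pyfaidx import Fasta

    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    out: dict[str, str] = {}
    for iv in intervals:
        if iv.chrom not in fasta:
            raise KeyError(f"chromosome {iv.chrom!r} absent from FASTA {fasta_path}")
        chrom_len = len(fasta[iv.chrom])
        if iv.end > chrom_len:
            raise ValueError(
                f"interval [{iv.start}, {iv.end}) off the end of {iv.chrom} "
                f"(length {chrom_len})"
            )
        seq = str(fasta[iv.chrom][iv.start : iv.end])
        if len(seq) != iv.length:
            raise ValueError(f"short extraction for {iv.region_id or iv.chrom}")
        out[iv.region_id or f"{iv.chrom}:{iv.start}-{iv.end}"] = seq
    return out


def _strand_scores(codes: np.ndarray, probs: np.ndarray) -> float:
    """Sum of probability products over all windows of one strand."""
    w = probs.shape[1]
    if codes.size < w:
        return 0.0
    # 5th row of zeros makes any window containing a non-ACGT base score 0
    padded = np.vstack([probs, np.zeros((1, w))])
    windows = sliding_window_view(codes, w)
    return float(padded[windows, np.arange(w)].prod(axis=1).sum())


def affinity(
    sequence: str,
    motif: MotifMatrix,
    background: Sequence[float] | None = None,
) -> float:
    """Occupancy-style affinity: sum of probability products over every window
    on the forward strand plus every window on the reverse complement.

    ``background`` is accepted for interface symmetry (kept as scan metadata
    by :func:`affinity_matrix`); the score itself is a plain probability sum,
    and windows containing non-ACGT bases contribute 0.
    """
    w = motif.width
    if len(sequence) < w:
        warnings.warn(
            f"sequence shorter than motif {motif.motif_id} (len {len(sequence)} < {w}); "
            "affinity is 0",
            stacklevel=2,
        )
        return 0.0
    codes = encode_sequence(sequence)
    fwd = _strand_scores(codes, motif.probabilities)
    rc = _RC_CODE[codes][::-1]
    rev = _strand_scores(rc, motif.probabilities)
    return fwd + rev


def affinity_matrix(
    sequences: Mapping[str, str],
    motifs: Sequence[MotifMatrix],
    background: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Regions x motifs affinity matrix (the regression design matrix N)."""
    if not sequences:
        raise ValueError("no sequences provided")
    data = np.empty((len(sequences), len(motifs)))
    region_ids = list(sequences)
    for j, motif in enumerate(motifs):
        for i, rid in enumerate(region_ids):
            data[i, j] = affinity(sequences[rid], motif, background)
    out = pd.DataFrame(data, index=region_ids, columns=[m.motif_id for m in motifs])
    out.attrs["background"] = tuple(background) if background is not None else None
    out.attrs["strand_policy"] = "both"
    return out
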