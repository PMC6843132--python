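"""Log-odds scanning of DNA sequences with a CCAAT-box matrix.

The probability matrix is converted to a log-odds scoring matrix in bits
against a background base composition; windows on either strand scoring at
or above a threshold are reported as hits in top-strand, 0-based half-open
coordinates.  Ambiguous bases (anything outside A/C/G/T, e.g. N) score as
the background-weighted average of the column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .matrix import BASES, PWM

__all__ = [
    "ScoringMatrix",
    "MotifHit",
    "log_odds",
    "scan_sequence",
    "best_hit",
    "relative_threshold",
    "window_scores",
    "reverse_complement",
    "read_fasta_sequences",
    "write_hits_bed",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# base -> row index; 4 = ambiguous
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class ScoringMatrix:
    """Log-odds matrix in bits over a background composition."""

    matrix: np.ndarray            # (width, 4)
    background: np.ndarray        # (4,)
    source_pwm_id: str = "pwm"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise ValueError("scoring matrix must have shape (width >= 1, 4)")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("scoring matrix entries must be finite")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.matrix.min(axis=1).sum())

    def with_ambiguity_row(self) -> np.ndarray:
        """(width, 5) matrix whose 5th column scores ambiguous bases."""
        amb = self.matrix @ self.background
        return np.column_stack([self.matrix, amb])


@dataclass(frozen=True, order=True)
class MotifHit:
    seq_id: str
    offset: int       # 0-based start on the top strand
    strand: str       # "+" or "-"
    score: float      # bits


def log_odds(
    pwm: PWM,
    background: Sequence[float] | None = None,
    epsilon: float = 0.01,
) -> ScoringMatrix:
    """entry(j, b) = log2(max(p_j(b), epsilon) / background(b))."""
    if background is None:
        bg = np.full(4, 0.25)
    else:
        bg = np.asarray(background, dtype=float)
        if bg.shape != (4,) or np.any(bg <= 0) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be a positive probability 4-vector")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    matrix = np.log2(np.maximum(pwm.matrix, epsilon) / bg)
    return ScoringMatrix(matrix=matrix, background=bg, source_pwm_id=pwm.id)


def window_scores(sm: ScoringMatrix, seq: str, strand: str = "+") -> np.ndarray:
    """Scores of every window of width w on one strand.

    Minus-strand entry i is the score of the reverse complement of
    seq[i:i+w], so indices are top-strand offsets on both strands.
    """
    w = sm.width
    codes = encode_sequence(seq)
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0)
    m5 = sm.with_ambiguity_row()
    if strand == "-":
        # complement base b scores via column 3 - b (ambiguous stays 4),
        # position j of the window reads matrix row w-1-j
        comp = np.where(codes < 4, 3 - codes, 4)
        scores = np.zeros(n)
        for j in range(w):
            scores += m5[w - 1 - j][comp[j: j + n]]
        return scores
    scores = np.zeros(n)
    for j in range(w):
        scores += m5[j][codes[j: j + n]]
    return scores


def scan_sequence(
    sm: ScoringMatrix,
    seq: str,
    threshold: float,
    strands: str = "both",
    seq_id: str = "seq",
) -> list[MotifHit]:
    """All windows scoring >= threshold, in ascending offset ('+' before '-')."""
    if strands not in ("+", "-", "both"):
        raise ValueError("strands must be '+', '-' or 'both'")
    if len(seq) < sm.width:
        warnings.warn(
            f"sequence {seq_id!r} shorter than matrix width {sm.width}; no windows",
            stacklevel=2,
        )
        return []
    hits: list[MotifHit] = []
    wanted = ("+", "-") if strands == "both" else (strands,)
    for strand in wanted:
        scores = window_scores(sm, seq, strand)
        for offset in np.nonzero(scores >= threshold)[0]:
            hits.append(MotifHit(seq_id, int(offset), strand, float(scores[offset])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def best_hit(sm: ScoringMatrix, seq: str, seq_id: str = "seq") -> MotifHit:
    """Maximum-score window over both strands.

    Ties break to the lowest offset, then to the '+' strand.
    """
    if len(seq) < sm.width:
        raise ValueError(f"sequence shorter than matrix width {sm.width}")
    plus = window_scores(sm, seq, "+")
    minus = window_scores(sm, seq, "-")
    best = None
    for strand, scores in (("+", plus), ("-", minus)):
        i = int(np.argmax(scores))
        cand = MotifHit(seq_id, i, strand, float(scores[i]))
        if (
            best is None
            or cand.score > best.score + 1e-12
            or (abs(cand.score - best.score) <= 1e-12
                and (cand.offset, cand.strand) < (best.offset, best.strand))
        ):
            best = cand
    return best


def relative_threshold(sm: ScoringMatrix, fraction: float) -> float:
    """min + fraction * (max - min) of the achievable score range."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    return sm.min_score + fraction * (sm.max_score - sm.min_score)


# ---------------------------------------------------------------------------
# I/O


def read_fasta_sequences(path) -> list[tuple[str, str]]:
    """Read a (small) FASTA file into (id, uppercase sequence) pairs."""
    out: list[tuple[str, str]] = []
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    out.append((name, "".join(chunks).upper()))
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        out.append((name, "".join(chunks).upper()))
    return out


def write_hits_bed(hits: Iterable[MotifHit], sm: ScoringMatrix, path,
                   name: str | None = None) -> None:
    """Write hits as BED6; scores are scaled to [0, 1000] over the matrix range."""
    lo, hi = sm.min_score, sm.max_score
    span = hi - lo or 1.0
    with open(path, "w") as fh:
        for h in hits:
            bed_score = int(round(1000 * (h.score - lo) / span))
            bed_score = min(max(bed_score, 0), 1000)
            fh.write(
                f"{h.seq_id}\t{h.offset}\t{h.offset + sm.width}\t"
                f"{name or sm.source_pwm_id}\t{bed_score}\t{h.strand}\n"
            )
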