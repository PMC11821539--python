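"""JASPAR position-weight matrices and log-odds motif scanning.

A position frequency matrix (PFM) of per-position nucleotide counts is
smoothed with a background-distributed pseudocount,

    P(b, j) = (count(b, j) + pseudocount * background(b)) / (total(j) + pseudocount),

and converted to a base-2 log-odds position weight matrix
``log2(P / background)``. Scanning slides the PWM over both strands and
keeps windows whose score clears a fraction of the matrix's dynamic range:

    score >= min_score + threshold_fraction * (max_score - min_score).

Windows containing ambiguous bases are skipped; minus-strand hits are
reported in plus-strand coordinates (0-based, half-open).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import motifs as bio_motifs

__all__ = ["PWM", "MotifHit", "parse_jaspar", "parse_jaspar_all", "pwm_scan"]

_ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_ALPHABET)}
UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


@dataclass
class PWM:
    """A position weight model derived from JASPAR-style counts.

    ``counts`` has shape (4, L) with rows in A, C, G, T order.
    """

    motif_id: str
    name: str
    counts: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.asarray(UNIFORM_BACKGROUND))
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(f"{self.motif_id}: counts must be 4 x L")
        if self.counts.shape[1] < 1:
            raise ValueError(f"{self.motif_id}: motif length must be >= 1")
        if np.any(self.counts < 0):
            raise ValueError(f"{self.motif_id}: negative counts")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if abs(self.background.sum() - 1.0) > 1e-9 or np.any(self.background <= 0):
            raise ValueError("background must be positive and sum to 1")

    @property
    def length(self) -> int:
        return int(self.counts.shape[1])

    @property
    def probabilities(self) -> np.ndarray:
        totals = self.counts.sum(axis=0, keepdims=True)
        return (self.counts + self.pseudocount * self.background[:, None]) / (
            totals + self.pseudocount)

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probabilities / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.counts.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        return PWM(motif_id=self.motif_id, name=self.name,
                   counts=self.counts[::-1, ::-1].copy(),
                   background=self.background[::-1].copy(),
                   pseudocount=self.pseudocount)

    def to_jaspar(self) -> str:
        lines = [f">{self.motif_id} {self.name}"]
        for i, base in enumerate(_ALPHABET):
            row = " ".join(f"{int(c) if c == int(c) else c:>6}"
                           for c in self.counts[i])
            lines.append(f"{base} [{row} ]")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class MotifHit:
    """A scored PWM occurrence in plus-strand, 0-based half-open coordinates."""

    seq_id: str
    start: int
    end: int
    strand: str
    score: float
    motif_id: str

    def to_bed(self) -> str:
        return (f"{self.seq_id}\t{self.start}\t{self.end}\t{self.motif_id}"
                f"\t{self.score:.4f}\t{self.strand}")


def parse_jaspar_all(
    pfm_text: str,
    background=UNIFORM_BACKGROUND,
    pseudocount: float = 1.0,
) -> list[PWM]:
    """Parse every motif in a JASPAR PFM text block."""
    try:
        parsed = bio_motifs.parse(io.StringIO(pfm_text), "jaspar")
    except Exception as exc:  # noqa: BLE001 - rewrap parser diagnostics
        raise ValueError(f"malformed JASPAR PFM text: {exc}") from exc
    if not parsed:
        raise ValueError("no motifs found in JASPAR text")
    out = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in _ALPHABET], dtype=float)
        out.append(PWM(motif_id=m.matrix_id or m.name, name=m.name,
                       counts=counts, background=np.asarray(background),
                       pseudocount=pseudocount))
    return out


def parse_jaspar(
    pfm_text: str,
    background=UNIFORM_BACKGROUND,
    pseudocount: float = 1.0,
) -> PWM:
    """Parse a single-motif JASPAR PFM text block into a PWM."""
    pwms = parse_jaspar_all(pfm_text, background, pseudocount)
    if len(pwms) != 1:
        raise ValueError(f"expected one motif, found {len(pwms)}")
    return pwms[0]


def _encode(sequence: str) -> np.ndarray:
    """Map a sequence to 0..3 indices; anything outside ACGT becomes -1."""
    table = np.full(256, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _window_scores(idx: np.ndarray, lo: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores for every window plus a validity mask (no ambiguous base)."""
    L = lo.shape[1]
    n_win = idx.size - L + 1
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    safe = np.where(idx < 0, 0, idx)
    for j in range(L):
        col = idx[j:j + n_win]
        valid &= col >= 0
        scores += lo[safe[j:j + n_win], j]
    return scores, valid


def pwm_scan(
    sequence: str,
    pwm: PWM,
    threshold_fraction: float = 0.8,
    both_strands: bool = True,
    seq_id: str = "seq",
) -> list[MotifHit]:
    """All PWM occurrences scoring above the fractional-range threshold.

    Hits are sorted by (start, strand); a sequence shorter than the motif
    yields an empty list.
    """
    if not (0 < threshold_fraction <= 1):
        raise ValueError("threshold_fraction must lie in (0, 1]")
    L = pwm.length
    idx = _encode(sequence)
    if idx.size < L:
        return []
    cutoff = pwm.min_score + threshold_fraction * (pwm.max_score - pwm.min_score)
    hits: list[MotifHit] = []
    lo = pwm.log_odds
    scores, valid = _window_scores(idx, lo)
    for i in np.nonzero(valid & (scores >= cutoff - 1e-12))[0]:
        hits.append(MotifHit(seq_id, int(i), int(i) + L, "+",
                             float(scores[i]), pwm.motif_id))
    if both_strands:
        lo_rc = lo[::-1, ::-1]
        scores_rc, valid_rc = _window_scores(idx, lo_rc)
        for i in np.nonzero(valid_rc & (scores_rc >= cutoff - 1e-12))[0]:
            hits.append(MotifHit(seq_id, int(i), int(i) + L, "-",
                                 float(scores_rc[i]), pwm.motif_id))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits
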