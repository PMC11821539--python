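"""Independent brute-force oracles used to check the library implementations.

Everything here is written from first principles (explicit loops, textbook
formulas) and deliberately shares no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def pearson_brute(x, y) -> float:
    """Textbook covariance-formula Pearson r over complete pairs."""
    pairs = [(a, b) for a, b in zip(x, y)
             if not (math.isnan(a) or math.isnan(b))]
    n = len(pairs)
    if n < 2:
        return float("nan")
    xs = [a for a, _ in pairs]
    ys = [b for _, b in pairs]
    mx = sum(xs) / n
    my = sum(ys) / n
    cov = sum((a - mx) * (b - my) for a, b in pairs)
    vx = sum((a - mx) ** 2 for a in xs)
    vy = sum((b - my) ** 2 for b in ys)
    if vx == 0 or vy == 0:
        return float("nan")
    return cov / math.sqrt(vx * vy)


def corr_p_brute(r: float, n: int) -> float:
    """Two-sided p for Pearson r via the t transform, scipy CDF only."""
    from scipy.stats import t as tdist
    if n < 3 or math.isnan(r):
        return float("nan")
    if abs(r) >= 1:
        return 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return 2 * (1 - tdist.cdf(abs(t), n - 2))


def scan_brute(sequence: str, log_odds: np.ndarray, cutoff: float,
               both_strands: bool = True,
               tol: float = 1e-12) -> set[tuple[int, str]]:
    """Exhaustive per-window PWM scoring; returns {(start, strand)}.

    ``tol`` mirrors the scanner's documented score tolerance at the cutoff
    (floating-point summation order differs between implementations).
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    index = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = log_odds.shape[1]
    seq = sequence.upper()
    hits = set()
    for i in range(len(seq) - L + 1):
        window = seq[i:i + L]
        if any(b not in index for b in window):
            continue
        score = sum(log_odds[index[b], j] for j, b in enumerate(window))
        if score >= cutoff - tol:
            hits.add((i, "+"))
        if both_strands:
            rc = "".join(comp[b] for b in reversed(window))
            score_rc = sum(log_odds[index[b], j] for j, b in enumerate(rc))
            if score_rc >= cutoff - tol:
                hits.add((i, "-"))
    return hits


def overlap_brute(a_intervals, b_intervals, min_overlap=1):
    """Quadratic all-pairs interval overlap; intervals are (chrom, start, end)."""
    out = set()
    for i, (ca, sa, ea) in enumerate(a_intervals):
        for j, (cb, sb, eb) in enumerate(b_intervals):
            if ca == cb and min(ea, eb) - max(sa, sb) >= min_overlap:
                out.add((i, j))
    return out


def coloc_brute(a_points, b_points, threshold) -> int:
    """All-pairs Euclidean colocalization count of a-points."""
    count = 0
    for p in a_points:
        for q in b_points:
            d = math.sqrt(sum((pi - qi) ** 2 for pi, qi in zip(p, q)))
            if d <= threshold:
                count += 1
                break
    return count


def profile_bins_brute(values, n_bins) -> np.ndarray:
    """Fine-resampling rebinning oracle: split each sample into 1000 slivers."""
    values = np.asarray(values, dtype=float)
    sub = 1000
    fine = np.repeat(values / sub, sub)  # mass per sliver
    length = values.size
    edges = np.linspace(0, length, n_bins + 1)
    out = np.zeros(n_bins)
    sliver_width = 1.0 / sub
    for i, m in enumerate(fine):
        lo = i * sliver_width
        hi = lo + sliver_width
        # assign sliver mass to bins proportionally to overlap
        b0 = int(np.searchsorted(edges, lo, side="right")) - 1
        b1 = int(np.searchsorted(edges, hi, side="left")) - 1
        b0 = min(max(b0, 0), n_bins - 1)
        b1 = min(max(b1, 0), n_bins - 1)
        if b0 == b1:
            out[b0] += m
        else:
            split = edges[b0 + 1]
            out[b0] += m * (split - lo) / sliver_width
            out[b1] += m * (hi - split) / sliver_width
    return out / values.sum()
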