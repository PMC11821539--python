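"""Synthetic fixtures with known ground truth for every pipeline stage.

Three generators emulate the data the analyses consume:

* ``simulate_activity`` — per-genotype region-activity tables drawn from a
  multivariate normal with a planted correlation structure, shifted and
  scaled to realistic FOS densities and floored at zero.
* ``simulate_sequences`` — a uniform-background genome with motif
  consensi written in at chosen positions and labelled ATAC / H3K27ac
  peaks, together with the exact candidate list the enhancer screen must
  recover.
* ``simulate_alignment`` — MAF blocks over a window where each
  non-reference species differs from the reference at a planted mismatch
  fraction, so stitched pairwise distances are known in closed form.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from vlptools.enhancer import DEFAULT_CELL_CLASS, DEFAULT_STAGE_ORDER, stage_rank
from vlptools.quant import ActivityTable

__all__ = [
    "ActivitySimSpec", "SequenceSimSpec", "AlignmentSimSpec",
    "SimulatedSequences", "simulate_activity", "simulate_sequences",
    "simulate_alignment",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


# ---------------------------------------------------------------------------
# activity tables


@dataclass
class ActivitySimSpec:
    """Planted design for a per-genotype region-activity cohort.

    ``sigma_per_group`` maps each group to its regions x regions
    correlation matrix (symmetric, unit diagonal, positive semi-definite);
    ``mean_per_group`` maps each group to per-region mean densities
    (cells/mm^3, positive); ``noise_sd`` is the marginal standard
    deviation, scalar or per-region.
    """

    groups: list[str]
    n_per_group: int
    regions: list[str]
    region_groups: dict[str, str]
    sigma_per_group: dict[str, np.ndarray]
    mean_per_group: dict[str, np.ndarray]
    noise_sd: float | np.ndarray = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 4:
            raise ValueError("n_per_group must be >= 4 (Fisher-z SE needs n > 3)")
        k = len(self.regions)
        for g in self.groups:
            sigma = np.asarray(self.sigma_per_group[g], dtype=float)
            if sigma.shape != (k, k):
                raise ValueError(f"sigma for group {g!r} is not {k} x {k}")
            if not np.allclose(sigma, sigma.T, atol=1e-10):
                raise ValueError(f"sigma for group {g!r} is not symmetric")
            if not np.allclose(np.diag(sigma), 1.0, atol=1e-10):
                raise ValueError(f"sigma for group {g!r} lacks a unit diagonal")
            if np.linalg.eigvalsh(sigma).min() < -1e-8:
                raise ValueError(
                    f"sigma for group {g!r} is not positive semi-definite")
            self.sigma_per_group[g] = sigma
            mean = np.asarray(self.mean_per_group[g], dtype=float)
            if mean.shape != (k,) or np.any(mean <= 0):
                raise ValueError(f"means for group {g!r} must be {k} positive values")
            self.mean_per_group[g] = mean
        missing = [r for r in self.regions if r not in self.region_groups]
        if missing:
            raise ValueError(f"regions without a broader-area label: {missing}")


def _psd_factor(sigma: np.ndarray) -> np.ndarray:
    """Factor F with F @ F.T = sigma, valid for semi-definite matrices."""
    w, v = np.linalg.eigh(sigma)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def simulate_activity(spec: ActivitySimSpec) -> ActivityTable:
    """Draw a cohort table from the planted per-group correlation structure.

    Values are multivariate normal, scaled to the requested means and
    marginal SDs, then floored at 0 (densities are non-negative). The
    fraction of clipped values is recorded on the returned table and
    should stay below 1% under realistic means; clipping beyond that
    distorts the planted correlations.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.regions)
    sd = np.broadcast_to(np.asarray(spec.noise_sd, dtype=float), (k,))
    frames = []
    group_labels = []
    clipped = 0
    total = 0
    for g in spec.groups:
        factor = _psd_factor(spec.sigma_per_group[g])
        z = rng.standard_normal((spec.n_per_group, k)) @ factor.T
        x = spec.mean_per_group[g] + sd * z
        clipped += int((x < 0).sum())
        total += x.size
        x = np.clip(x, 0.0, None)
        idx = [f"{g}_{i + 1}" for i in range(spec.n_per_group)]
        frames.append(pd.DataFrame(x, index=idx, columns=spec.regions))
        group_labels.extend([g] * spec.n_per_group)
    values = pd.concat(frames)
    groups = pd.Series(group_labels, index=values.index, name="group")
    meta = {r: (r, spec.region_groups[r]) for r in spec.regions}
    return ActivityTable(values=values, groups=groups, region_meta=meta,
                         clip_fraction=clipped / total if total else 0.0)


# ---------------------------------------------------------------------------
# sequences, peaks, and enhancer ground truth


@dataclass
class SequenceSimSpec:
    """Planted genome design for the candidate-enhancer screen.

    ``planted_motifs`` is a list of ``(consensus, position, strand)``;
    ``planted_peaks`` of ``(start, end, assay, stage, cell_class)`` with
    assay in {ATAC, H3K27ac}. After planting, any background window within
    ``scrub_hamming`` mismatches of a planted consensus (either strand) is
    resampled, so the planted sites are the only near-consensus
    occurrences and the expected screen output is exact by construction.
    """

    genome_length: int
    planted_motifs: list[tuple[str, int, str]]
    planted_peaks: list[tuple[int, int, str, str, str]]
    seed: int = 0
    chrom: str = "chrS"
    cell_class: str = DEFAULT_CELL_CLASS
    stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER
    min_stage: str = "PCD13.5"
    scrub_hamming: int = 2

    def __post_init__(self) -> None:
        seen = set()
        for consensus, pos, strand in self.planted_motifs:
            if strand not in "+-":
                raise ValueError(f"strand must be + or -, got {strand!r}")
            if pos < 0 or pos + len(consensus) > self.genome_length:
                raise ValueError(
                    f"motif at {pos} exceeds genome of {self.genome_length} bp")
            if pos in seen:
                raise ValueError(f"two motifs planted at identical position {pos}")
            seen.add(pos)
        for start, end, assay, stage, _ in self.planted_peaks:
            if not (0 <= start < end <= self.genome_length):
                raise ValueError(f"peak [{start}, {end}) outside genome")
            if assay not in ("ATAC", "H3K27ac"):
                raise ValueError(f"unknown assay label {assay!r}")
            if assay == "ATAC":
                stage_rank(stage, self.stage_order)


@dataclass
class SimulatedSequences:
    """FASTA + BED text plus the expected enhancer-candidate intervals."""

    fasta: str
    bed: str
    truth: list[tuple[str, int, int]]
    sequence: str


def _hamming_windows(seq: np.ndarray, pattern: str) -> np.ndarray:
    """Hamming distance of every window of ``len(pattern)`` against it."""
    L = len(pattern)
    pat = np.frombuffer(pattern.encode(), dtype="S1")
    n = seq.size - L + 1
    if n <= 0:
        return np.empty(0, dtype=int)
    dist = np.zeros(n, dtype=int)
    for j in range(L):
        dist += seq[j:j + n] != pat[j]
    return dist


def simulate_sequences(spec: SequenceSimSpec) -> SimulatedSequences:
    """Emit a genome, labelled peaks, and the exact expected candidate list.

    Ground truth is derived purely from the planted design: an ATAC peak of
    the target cell class, accessible at >= ``min_stage`` in at least one
    recorded stage, containing a planted motif fully inside it and
    overlapping >= 1 bp of an H3K27ac peak. The background scrub (see
    class docstring) guarantees no unplanted near-consensus occurrence can
    add spurious calls for a sharply peaked PWM.
    """
    rng = np.random.default_rng(spec.seed)
    seq = rng.choice(_BASES, size=spec.genome_length)
    planted_intervals = []
    for consensus, pos, strand in spec.planted_motifs:
        written = consensus.upper() if strand == "+" else _revcomp(consensus)
        seq[pos:pos + len(written)] = np.frombuffer(written.encode(), dtype="S1")
        planted_intervals.append((pos, pos + len(written)))
    _scrub_background(seq, spec, planted_intervals, rng)
    sequence = seq.tobytes().decode()

    bed_lines = []
    for i, (start, end, assay, stage, cell_class) in enumerate(spec.planted_peaks):
        bed_lines.append(f"{spec.chrom}\t{start}\t{end}\tpeak_{i}\t0\t."
                         f"\t{assay}\t{stage}\t{cell_class}")
    bed = "\n".join(bed_lines) + "\n" if bed_lines else ""

    truth = _expected_candidates(spec, planted_intervals)
    fasta_lines = [f">{spec.chrom}"]
    fasta_lines.extend(sequence[i:i + 60] for i in range(0, len(sequence), 60))
    return SimulatedSequences(fasta="\n".join(fasta_lines) + "\n", bed=bed,
                              truth=truth, sequence=sequence)


def _scrub_background(
    seq: np.ndarray,
    spec: SequenceSimSpec,
    planted_intervals: list[tuple[int, int]],
    rng: np.random.Generator,
) -> None:
    """Resample windows near-matching any planted consensus off planted sites."""
    patterns = {m[0].upper() for m in spec.planted_motifs}
    patterns |= {_revcomp(p) for p in patterns}
    for _ in range(50):  # converges in one or two passes in practice
        dirty: set[int] = set()
        for pat in patterns:
            L = len(pat)
            dist = _hamming_windows(seq, pat)
            for i in np.nonzero(dist <= spec.scrub_hamming)[0]:
                i = int(i)
                if any(i < e and i + L > s for s, e in planted_intervals):
                    continue
                dirty.update(range(i, i + L))
        if not dirty:
            return
        pos = sorted(dirty)
        seq[pos] = rng.choice(_BASES, size=len(pos))
    raise RuntimeError("background scrub failed to converge")


def _expected_candidates(
    spec: SequenceSimSpec,
    planted_intervals: list[tuple[int, int]],
) -> list[tuple[str, int, int]]:
    min_rank = stage_rank(spec.min_stage, spec.stage_order)
    atac: dict[tuple[int, int], set[str]] = {}
    k27 = []
    for start, end, assay, stage, cell_class in spec.planted_peaks:
        if assay == "H3K27ac":
            k27.append((start, end))
        elif cell_class == spec.cell_class:
            atac.setdefault((start, end), set()).add(stage)
    truth = []
    for (start, end), stages in sorted(atac.items()):
        if not any(stage_rank(s, spec.stage_order) >= min_rank for s in stages):
            continue
        if not any(ms >= start and me <= end for ms, me in planted_intervals):
            continue
        if not any(min(end, ke) - max(start, ks) >= 1 for ks, ke in k27):
            continue
        truth.append((spec.chrom, start, end))
    return truth


# ---------------------------------------------------------------------------
# alignments


@dataclass
class AlignmentSimSpec:
    """Planted divergence design for MAF stitching and distance recovery.

    The first species is the reference. ``per_pair_divergence`` maps each
    non-reference species to the fraction of window positions at which it
    mismatches the reference (count rounded to the nearest integer).
    ``block_lengths`` must sum to the window length.
    """

    species: list[str]
    window: tuple[str, int, int]
    per_pair_divergence: dict[str, float]
    block_lengths: list[int]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.species) < 2:
            raise ValueError("at least 2 species required")
        chrom, start, end = self.window
        if end <= start:
            raise ValueError("window end must exceed start")
        if sum(self.block_lengths) != end - start:
            raise ValueError(
                f"block lengths sum to {sum(self.block_lengths)}, "
                f"window spans {end - start}")
        for sp in self.species[1:]:
            f = self.per_pair_divergence.get(sp, 0.0)
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"divergence for {sp!r} must lie in [0, 1]")


def simulate_alignment(spec: AlignmentSimSpec) -> str:
    """Emit MAF text whose stitched distances are sqrt(planted fraction).

    Each non-reference species copies the reference and is substituted at
    ``round(divergence * window_length)`` distinct positions (to a
    different base), so identity against the reference is exact by
    construction. No gaps are planted.
    """
    rng = np.random.default_rng(spec.seed)
    chrom, start, end = spec.window
    length = end - start
    ref = spec.species[0]
    seqs = {ref: rng.choice(_BASES, size=length)}
    for sp in spec.species[1:]:
        frac = spec.per_pair_divergence.get(sp, 0.0)
        n_mut = int(round(frac * length))
        s = seqs[ref].copy()
        if n_mut:
            positions = rng.choice(length, size=n_mut, replace=False)
            for p in positions:
                current = s[p]
                options = _BASES[_BASES != current]
                s[p] = rng.choice(options)
        seqs[sp] = s
    lines = ["##maf version=1 scoring=synthetic", ""]
    offset = 0
    for blen in spec.block_lengths:
        lines.append("a score=0.000000")
        for sp in spec.species:
            text = seqs[sp][offset:offset + blen].tobytes().decode()
            lines.append(
                f"s {sp}.{chrom} {start + offset} {blen} + {end} {text}")
        lines.append("")
        offset += blen
    return "\n".join(lines) + "\n"
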