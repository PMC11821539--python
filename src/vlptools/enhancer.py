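"""Candidate-enhancer calling from accessibility, H3K27ac, and motif evidence.

A candidate enhancer is an ATAC peak of the target cell class that is
accessible at or after a minimum developmental stage, contains at least one
SOX-family motif occurrence fully inside it, and overlaps at least one
H3K27ac peak. All coordinates are 0-based half-open (BED semantics), so
abutting intervals do not overlap. Developmental stages are ordered through
an explicit stage list, never lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from vlptools.motifs import MotifHit

__all__ = [
    "Peak", "PeakSet", "EnhancerCandidate", "DEFAULT_STAGE_ORDER",
    "DEFAULT_CELL_CLASS", "read_peaks", "intersect_intervals",
    "call_candidates",
]

#: Post-conception-day stage ordering used by the developmental screens.
DEFAULT_STAGE_ORDER = (
    "PCD11.5", "PCD12.5", "PCD13.5", "PCD14.5", "PCD15.5",
    "PCD16.5", "PCD17.5", "PCD18.5", "PD0",
)

DEFAULT_CELL_CLASS = "migrating excitatory neurons"


@dataclass(frozen=True)
class Peak:
    """A labelled genomic interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    assay: str = ""
    stage: str = ""
    cell_class: str = ""
    name: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} has start >= end")
        if self.start < 0:
            raise ValueError("interval start must be >= 0")

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def to_bed(self) -> str:
        return (f"{self.chrom}\t{self.start}\t{self.end}\t{self.name}\t0\t."
                f"\t{self.assay}\t{self.stage}\t{self.cell_class}")


class PeakSet:
    """Sorted collection of labelled peaks with per-chromosome lookup."""

    def __init__(self, peaks) -> None:
        self.peaks: list[Peak] = sorted(
            peaks, key=lambda p: (p.chrom, p.start, p.end, p.assay, p.stage))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def by_assay(self, assay: str) -> "PeakSet":
        return PeakSet(p for p in self.peaks if p.assay == assay)

    def trees(self) -> dict[str, IntervalTree]:
        out: dict[str, IntervalTree] = {}
        for i, p in enumerate(self.peaks):
            out.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, i)
        return out

    def to_bed(self) -> str:
        return "\n".join(p.to_bed() for p in self.peaks) + "\n"


@dataclass
class EnhancerCandidate:
    """An ATAC-anchored candidate with its motif and H3K27ac evidence."""

    chrom: str
    start: int
    end: int
    stages: tuple[str, ...]
    motif_hits: list[MotifHit] = field(default_factory=list)
    k27_overlaps: list[Peak] = field(default_factory=list)

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def read_peaks(bed_text: str) -> PeakSet:
    """Parse BED6+3 text (chrom start end name score strand assay stage cell_class)."""
    peaks = []
    for ln, line in enumerate(bed_text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"BED line {ln}: fewer than 3 columns")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        name = parts[3] if len(parts) > 3 else "."
        assay = parts[6] if len(parts) > 6 else ""
        stage = parts[7] if len(parts) > 7 else ""
        cell_class = parts[8] if len(parts) > 8 else ""
        peaks.append(Peak(chrom, start, end, assay=assay, stage=stage,
                          cell_class=cell_class, name=name))
    return PeakSet(peaks)


def intersect_intervals(
    a: PeakSet,
    b: PeakSet,
    min_overlap_bp: int = 1,
) -> list[tuple[Peak, Peak, int, int]]:
    """All (a, b) peak pairs overlapping by >= ``min_overlap_bp`` bases.

    Overlap is half-open arithmetic: ``min(ends) - max(starts)``; abutting
    intervals share zero bases and never pair. Returns
    ``(a_peak, b_peak, inter_start, inter_end)`` tuples sorted by the a peak.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    trees = b.trees()
    out = []
    for pa in a:
        tree = trees.get(pa.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(pa.start, pa.end)):
            pb = b.peaks[hit.data]
            lo, hi = max(pa.start, pb.start), min(pa.end, pb.end)
            if hi - lo >= min_overlap_bp:
                out.append((pa, pb, lo, hi))
    return out


def stage_rank(stage: str, stage_order=DEFAULT_STAGE_ORDER) -> int:
    """Index of a stage label in the explicit developmental ordering."""
    try:
        return list(stage_order).index(stage)
    except ValueError:
        raise ValueError(
            f"unknown stage label {stage!r}; known ordering: {list(stage_order)}"
        ) from None


def call_candidates(
    atac: PeakSet,
    k27: PeakSet,
    hits: list[MotifHit],
    min_stage: str = "PCD13.5",
    stage_order=DEFAULT_STAGE_ORDER,
    cell_class: str = DEFAULT_CELL_CLASS,
    require_all_stages: bool = False,
) -> list[EnhancerCandidate]:
    """Join the three evidence tracks into candidate-enhancer calls.

    An ATAC peak (possibly recorded once per accessible stage) qualifies
    when its cell class matches, it is accessible at >= ``min_stage`` in at
    least one recorded stage (every recorded stage if
    ``require_all_stages``), at least one motif hit lies fully inside it,
    and it overlaps >= 1 bp of an H3K27ac peak. Output is deterministic,
    ordered by (chrom, start).
    """
    min_rank = stage_rank(min_stage, stage_order)
    by_interval: dict[tuple[str, int, int], set[str]] = {}
    for p in atac:
        if p.cell_class != cell_class:
            continue
        stage_rank(p.stage, stage_order)  # validate label eagerly
        by_interval.setdefault(p.interval, set()).add(p.stage)
    k27set = k27.by_assay("H3K27ac") if any(p.assay for p in k27) else k27
    k27_trees = k27set.trees()
    k27_peaks = k27set.peaks
    candidates = []
    for (chrom, start, end), stages in sorted(by_interval.items()):
        ranks = [stage_rank(s, stage_order) for s in stages]
        ok = (all(r >= min_rank for r in ranks) if require_all_stages
              else any(r >= min_rank for r in ranks))
        if not ok:
            continue
        inside = [h for h in hits
                  if h.seq_id == chrom and h.start >= start and h.end <= end]
        if not inside:
            continue
        tree = k27_trees.get(chrom)
        overlaps = []
        if tree is not None:
            for hit in sorted(tree.overlap(start, end)):
                pb = k27_peaks[hit.data]
                if min(end, pb.end) - max(start, pb.start) >= 1:
                    overlaps.append(pb)
        if not overlaps:
            continue
        candidates.append(EnhancerCandidate(
            chrom=chrom, start=start, end=end,
            stages=tuple(sorted(stages, key=lambda s: stage_rank(s, stage_order))),
            motif_hits=sorted(inside, key=lambda h: (h.start, h.strand)),
            k27_overlaps=overlaps))
    return candidates
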