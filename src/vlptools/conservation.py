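"""MAF stitching and pairwise alignment distances for enhancer windows.

Multiple-alignment blocks (e.g. MULTIZ60) covering a genomic window are
restricted to the window, concatenated in reference order, and padded with
gaps for species absent from a block, yielding one gapped sequence per
species convertible to aligned FASTA. Pairwise distance between species is

    d = sqrt(1 - identity),

with identity computed over comparable columns only: positions where both
sequences carry an unambiguous nucleotide (case-insensitive; gaps and
ambiguity codes such as N are excluded). Pairs with no comparable column
are reported missing.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import AlignIO

__all__ = [
    "AlignmentBlock", "StitchedAlignment", "DistanceMatrix",
    "read_maf", "stitch_maf", "pairwise_distance",
]

logger = logging.getLogger(__name__)

_NUCLEOTIDES = frozenset("ACGT")


@dataclass
class SpeciesRow:
    species: str
    chrom: str
    start: int
    size: int
    strand: str
    src_size: int
    text: str  # gapped sequence

    def __post_init__(self) -> None:
        ungapped = sum(1 for c in self.text if c != "-")
        if ungapped != self.size:
            raise ValueError(
                f"{self.species}.{self.chrom}: ungapped length {ungapped} "
                f"!= declared size {self.size}")


@dataclass
class AlignmentBlock:
    """One MAF 'a' block: equal-width gapped rows, one per species."""

    rows: list[SpeciesRow]
    score: float = 0.0

    def __post_init__(self) -> None:
        widths = {len(r.text) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"unequal row widths in block: {sorted(widths)}")

    @property
    def width(self) -> int:
        return len(self.rows[0].text)

    @property
    def reference(self) -> SpeciesRow:
        return self.rows[0]

    def row_for(self, species: str) -> SpeciesRow | None:
        for r in self.rows:
            if r.species == species:
                return r
        return None


@dataclass
class StitchedAlignment:
    """Per-species concatenated gapped sequences over a genomic window."""

    window: tuple[str, int, int]
    species: list[str]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        widths = {len(s) for s in self.sequences.values()}
        if len(widths) > 1:
            raise ValueError("stitched sequences have unequal lengths")

    @property
    def width(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def to_fasta(self) -> str:
        chrom, start, end = self.window
        out = []
        for sp in self.species:
            out.append(f">{sp} {chrom}:{start}-{end}")
            seq = self.sequences[sp]
            out.extend(seq[i:i + 60] for i in range(0, len(seq), 60))
        return "\n".join(out) + "\n"


@dataclass
class DistanceMatrix:
    species: list[str]
    matrix: pd.DataFrame
    n_comparable: pd.DataFrame

    def to_csv(self) -> str:
        buf = io.StringIO()
        self.matrix.to_csv(buf, index_label="species")
        return buf.getvalue()

    def to_phylip(self) -> str:
        lines = [f"{len(self.species)}"]
        for sp in self.species:
            vals = " ".join(
                "NA" if not np.isfinite(self.matrix.loc[sp, o])
                else f"{self.matrix.loc[sp, o]:.6f}" for o in self.species)
            lines.append(f"{sp:<10s} {vals}")
        return "\n".join(lines) + "\n"


def read_maf(maf_text: str) -> list[AlignmentBlock]:
    """Parse MAF text ('a'/'s' line dialect) into alignment blocks."""
    blocks = []
    for aln in AlignIO.parse(io.StringIO(maf_text), "maf"):
        rows = []
        for rec in aln:
            species, _, chrom = rec.id.partition(".")
            ann = rec.annotations
            rows.append(SpeciesRow(
                species=species, chrom=chrom, start=int(ann["start"]),
                size=int(ann["size"]),
                strand="+" if ann.get("strand", 1) in (1, "+") else "-",
                src_size=int(ann.get("srcSize", 0)), text=str(rec.seq)))
        if rows:
            blocks.append(AlignmentBlock(rows=rows))
    return blocks


def _ref_coordinates(row: SpeciesRow) -> np.ndarray:
    """Reference genomic coordinate of each column's base (-1 for gap columns)."""
    coords = np.full(len(row.text), -1, dtype=int)
    pos = row.start
    for i, c in enumerate(row.text):
        if c != "-":
            coords[i] = pos
            pos += 1
    return coords


def stitch_maf(
    blocks: list[AlignmentBlock],
    window: tuple[str, int, int],
    species: list[str],
) -> StitchedAlignment:
    """Restrict blocks to the window and concatenate them in reference order.

    The first species in ``species`` is the reference; blocks are keyed and
    ordered by its coordinates. Blocks entirely outside the window are
    skipped (logged); blocks overlapping on the reference are an error.
    A species absent from a block contributes gap characters for that
    block's in-window width.
    """
    if len(species) < 2:
        raise ValueError("stitching needs at least 2 species")
    chrom, w_start, w_end = window
    ref = species[0]
    in_window = []
    for blk in blocks:
        row = blk.row_for(ref)
        if row is None:
            raise ValueError(f"block lacks reference species {ref!r}")
        if row.chrom != chrom or row.start + row.size <= w_start or row.start >= w_end:
            logger.info("skipping block %s.%s:%d-%d outside window",
                        ref, row.chrom, row.start, row.start + row.size)
            continue
        in_window.append((row.start, row.start + row.size, blk))
    in_window.sort(key=lambda t: t[0])
    for (s1, e1, _), (s2, _, _) in zip(in_window, in_window[1:]):
        if s2 < e1:
            raise ValueError(
                f"blocks overlap on reference: [{s1}, {e1}) and [{s2}, ...)")
    parts: dict[str, list[str]] = {sp: [] for sp in species}
    for _, _, blk in in_window:
        coords = _ref_coordinates(blk.row_for(ref))
        keep = np.nonzero((coords >= w_start) & (coords < w_end))[0]
        if keep.size == 0:
            continue
        c0, c1 = int(keep[0]), int(keep[-1]) + 1
        width = c1 - c0
        for sp in species:
            row = blk.row_for(sp)
            parts[sp].append(row.text[c0:c1] if row is not None else "-" * width)
    return StitchedAlignment(
        window=window, species=list(species),
        sequences={sp: "".join(parts[sp]) for sp in species})


def pairwise_distance(aln: StitchedAlignment) -> DistanceMatrix:
    """sqrt(1 - identity) distances over pairwise-comparable columns."""
    if len(aln.species) < 2:
        raise ValueError("distance needs at least 2 species")
    sp = aln.species
    arrays = {s: np.frombuffer(aln.sequences[s].upper().encode(), dtype="S1")
              for s in sp}
    valid = {s: np.isin(arrays[s], [b"A", b"C", b"G", b"T"]) for s in sp}
    d = pd.DataFrame(0.0, index=sp, columns=sp)
    n = pd.DataFrame(0, index=sp, columns=sp)
    for i, a in enumerate(sp):
        for b in sp[i + 1:]:
            both = valid[a] & valid[b]
            n_cols = int(both.sum())
            n.loc[a, b] = n.loc[b, a] = n_cols
            if n_cols == 0:
                d.loc[a, b] = d.loc[b, a] = np.nan
                continue
            matches = int((arrays[a][both] == arrays[b][both]).sum())
            identity = matches / n_cols
            dist = float(np.sqrt(1.0 - identity))
            d.loc[a, b] = d.loc[b, a] = dist
    return DistanceMatrix(species=list(sp), matrix=d, n_comparable=n)
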