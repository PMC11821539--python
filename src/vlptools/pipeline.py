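"""End-to-end reproducible runs: simulate fixtures, analyse, write a manifest.

A run is described by a :class:`RunConfig` (YAML- or dict-round-trippable).
Each requested stage simulates its inputs, executes the analysis, and
writes plain-text artifacts into the output directory. A JSON manifest
records every parameter (including defaults), the seed, and the SHA-256 of
every file written, so re-running an identical config reproduces
byte-identical outputs and an identical manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from vlptools.conservation import pairwise_distance, read_maf, stitch_maf
from vlptools.enhancer import (DEFAULT_CELL_CLASS, DEFAULT_STAGE_ORDER,
                               call_candidates, read_peaks)
from vlptools.motifs import PWM, pwm_scan
from vlptools.network import build_graph, compare_groups, pearson_matrix
from vlptools.simulate import (ActivitySimSpec, AlignmentSimSpec,
                               SequenceSimSpec, simulate_activity,
                               simulate_alignment, simulate_sequences)

__all__ = ["RunConfig", "run_pipeline", "default_activity_spec",
           "default_sequence_spec", "default_alignment_spec", "demo_sox_pwm"]

ALL_STAGES = ("activity", "enhancer", "conservation")


@dataclass
class RunConfig:
    """Validated parameters for a full synthetic-demo pipeline run."""

    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    outdir: str = "vlp_run"
    # network stage
    r_cut: float = 0.85
    p_cut: float = 0.05
    alpha: float = 0.05
    signed: bool = True
    n_per_group: int = 4
    # enhancer stage
    threshold_fraction: float = 0.8
    min_stage: str = "PCD13.5"
    # quantification defaults carried for provenance
    coloc_threshold: float = 3.0
    n_bins: int = 200

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in ALL_STAGES]
        if bad:
            raise ValueError(f"unknown stages {bad}; known: {list(ALL_STAGES)}")
        for name, lo, hi in (("r_cut", -1, 1), ("p_cut", 0, 1),
                             ("alpha", 0, 1), ("threshold_fraction", 0, 1)):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.coloc_threshold < 0:
            raise ValueError("coloc_threshold must be >= 0")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.n_per_group < 4:
            raise ValueError("n_per_group must be >= 4")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        import yaml
        return cls.from_dict(yaml.safe_load(text) or {})

    def to_yaml(self) -> str:
        import yaml
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


def default_activity_spec(seed: int = 0, n_per_group: int = 4) -> ActivitySimSpec:
    """The demo cohort: 3 genotypes x n animals x 30 regions in 5 areas.

    Wild-type and heterozygote share a block-correlated structure (within-
    area r = 0.8); the knockout's interregional coupling is flattened to
    0.2, emulating a loss of coordinated activity.
    """
    areas = ["AMY", "CTX", "HIP", "TH", "HY"]
    regions = [f"{a}{i + 1}" for a in areas for i in range(6)]
    region_groups = {r: r[:-1] if r[-1].isdigit() else r for r in regions}
    region_groups = {r: next(a for a in areas if r.startswith(a)) for r in regions}
    k = len(regions)

    def block_sigma(r_within: float) -> np.ndarray:
        sigma = np.full((k, k), 0.05)
        for bi in range(len(areas)):
            s, e = bi * 6, (bi + 1) * 6
            sigma[s:e, s:e] = r_within
        np.fill_diagonal(sigma, 1.0)
        return sigma

    rng = np.random.default_rng(12345)  # fixed region means, not per-run noise
    means = rng.uniform(300.0, 900.0, size=k)
    groups = ["WT", "cHet", "cKO"]
    sig = {"WT": block_sigma(0.8), "cHet": block_sigma(0.8),
           "cKO": block_sigma(0.2)}
    mean_per_group = {"WT": means, "cHet": means * 0.9, "cKO": means * 0.7}
    return ActivitySimSpec(groups=groups, n_per_group=n_per_group,
                           regions=regions, region_groups=region_groups,
                           sigma_per_group=sig, mean_per_group=mean_per_group,
                           noise_sd=60.0, seed=seed)


def demo_sox_pwm() -> PWM:
    """A sharply peaked SOX-consensus-like PWM used by the synthetic demo.

    Counts 97:1:1:1 per column make every mismatch costly, so the planted
    consensus sites are the only credible hits at the default threshold.
    """
    consensus = "AACAATGGCGGT"
    counts = np.ones((4, len(consensus)))
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = 97
    return PWM(motif_id="SOXSIM.1", name="SOX-demo", counts=counts)


def default_sequence_spec(seed: int = 0) -> SequenceSimSpec:
    """50 kb demo genome with positive, stage-negative, and K27-negative peaks."""
    consensus = demo_sox_pwm().consensus
    return SequenceSimSpec(
        genome_length=50_000,
        planted_motifs=[(consensus, 10_200, "+"), (consensus, 20_150, "-"),
                        (consensus, 30_100, "+")],
        planted_peaks=[
            # true candidate: accessible late, motif inside, K27 overlap
            (10_000, 10_500, "ATAC", "PCD13.5", DEFAULT_CELL_CLASS),
            (10_300, 10_800, "H3K27ac", "", ""),
            # stage-filter negative: accessible too early only
            (20_000, 20_500, "ATAC", "PCD12.5", DEFAULT_CELL_CLASS),
            (20_100, 20_600, "H3K27ac", "", ""),
            # K27 abutment negative: half-open intervals do not overlap
            (30_000, 30_400, "ATAC", "PCD14.5", DEFAULT_CELL_CLASS),
            (30_400, 30_900, "H3K27ac", "", ""),
        ],
        seed=seed)


def default_alignment_spec(seed: int = 0) -> AlignmentSimSpec:
    """5 species, 400 bp window, 2 blocks, mismatch fractions 0/0.04/0.25/0.5."""
    return AlignmentSimSpec(
        species=["mm10", "hg38", "galGal6", "xenTro9", "danRer11"],
        window=("chr10", 1_000, 1_400),
        per_pair_divergence={"hg38": 0.0, "galGal6": 0.04,
                             "xenTro9": 0.25, "danRer11": 0.5},
        block_lengths=[200, 200], seed=seed)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(outdir: Path, name: str, text: str, manifest: dict) -> Path:
    path = outdir / name
    path.write_text(text)
    manifest["outputs"][name] = _sha256(path)
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages and return the manifest (also written).

    Outputs are plain text (CSV/TSV/BED/FASTA/MAF/GraphML); the manifest
    contains no timestamps, so identical configs yield identical manifests.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from vlptools import __version__  # deferred: avoids import cycle

    manifest: dict = {"config": config.to_dict(), "version": __version__,
                      "outputs": {}}

    if "activity" in config.stages:
        spec = default_activity_spec(seed=config.seed,
                                     n_per_group=config.n_per_group)
        table = simulate_activity(spec)
        manifest["activity_clip_fraction"] = table.clip_fraction
        _write(outdir, "activity.csv", table.to_csv(), manifest)
        corrs = {}
        for g in spec.groups:
            c = pearson_matrix(table, group=g)
            c = dataclasses.replace(c, group=g)
            corrs[g] = c
            _write(outdir, f"corr_r_{g}.csv", c.to_csv("r"), manifest)
            _write(outdir, f"corr_p_{g}.csv", c.to_csv("p"), manifest)
            graph = build_graph(c, r_cut=config.r_cut, p_cut=config.p_cut,
                                signed=config.signed)
            _write(outdir, f"graph_{g}.graphml", graph.to_graphml(), manifest)
            _write(outdir, f"edges_{g}.tsv", graph.edge_list_tsv(), manifest)
            manifest[f"edge_count_{g}"] = graph.edge_count
        comp = compare_groups(corrs["WT"], corrs["cKO"], alpha=config.alpha)
        _write(outdir, "compare_WT_vs_cKO.tsv", comp.to_tsv(), manifest)
        manifest["n_significant_pairs_WT_vs_cKO"] = int(
            comp.records["significant"].sum())

    if "enhancer" in config.stages:
        spec = default_sequence_spec(seed=config.seed)
        sim = simulate_sequences(spec)
        _write(outdir, "genome.fa", sim.fasta, manifest)
        _write(outdir, "peaks.bed", sim.bed, manifest)
        pwm = demo_sox_pwm()
        hits = pwm_scan(sim.sequence, pwm,
                        threshold_fraction=config.threshold_fraction,
                        seq_id=spec.chrom)
        _write(outdir, "motif_hits.bed",
               "\n".join(h.to_bed() for h in hits) + "\n", manifest)
        peaks = read_peaks(sim.bed)
        candidates = call_candidates(peaks.by_assay("ATAC"),
                                     peaks.by_assay("H3K27ac"), hits,
                                     min_stage=config.min_stage)
        cand_lines = ["chrom\tstart\tend\tstages\tn_motif_hits\tn_k27"]
        for c in candidates:
            cand_lines.append(f"{c.chrom}\t{c.start}\t{c.end}\t"
                              f"{','.join(c.stages)}\t{len(c.motif_hits)}\t"
                              f"{len(c.k27_overlaps)}")
        _write(outdir, "candidates.tsv", "\n".join(cand_lines) + "\n", manifest)
        manifest["n_candidates"] = len(candidates)
        manifest["candidates_match_truth"] = (
            [c.interval for c in candidates] == sim.truth)

    if "conservation" in config.stages:
        spec = default_alignment_spec(seed=config.seed)
        maf = simulate_alignment(spec)
        _write(outdir, "alignment.maf", maf, manifest)
        blocks = read_maf(maf)
        stitched = stitch_maf(blocks, spec.window, spec.species)
        _write(outdir, "stitched.fa", stitched.to_fasta(), manifest)
        dm = pairwise_distance(stitched)
        _write(outdir, "distances.csv", dm.to_csv(), manifest)
        _write(outdir, "distances.phy", dm.to_phylip(), manifest)
        ref = spec.species[0]
        manifest["distances_to_reference"] = {
            sp: round(float(dm.matrix.loc[ref, sp]), 10)
            for sp in spec.species[1:]}

    text = json.dumps(manifest, indent=2, sort_keys=True)
    (outdir / "manifest.json").write_text(text)
    return manifest
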