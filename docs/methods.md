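# Methods

## Activity tables and correlation networks

The substrate is an animals × regions table of FOS+ cell densities
(cells/mm³) with a genotype label per animal and a broader-area label per
region. Missing values are preserved as missing and handled by pairwise
deletion everywhere; nothing is imputed. Per-pair sample sizes are
recorded, so pairs may legitimately differ in n within one matrix.

Pearson r is computed pairwise-complete; two-sided p-values use the exact
t-transform t = r·√((n−2)/(1−r²)) with n−2 degrees of freedom. The
distributional choice is deliberate: it is the standard small-sample exact
test under bivariate normality, and a seeded permutation alternative
(`method="permutation"`, ≥ 10,000 shuffles recommended) is provided for
cohorts where normality is doubtful. Pairs with n < 3 or a constant region
get missing r/p. |r| = 1 maps to p = 0.

Graph construction keeps pairs with p < `p_cut` (default 0.05) and
r > `r_cut` (default 0.85). The signed rule is the default because the
published edge rule is stated as r > 0.85; `signed=False` switches to
|r| > 0.85 for workflows that visualize negative edges. Only one triangle
of the symmetric matrix is traversed, so duplicate undirected edges cannot
arise. A consequence worth stating: at n = 4 per group the two-sided 5%
critical correlation is r = 0.9500 (to 4 dp), so the p-filter strictly
dominates the r cutoff — the edge sets at (r > 0.85, p < 0.05) are a
subset of those at (r > 0.95, p ≤ 1). Both thresholds therefore remain
user-visible parameters, echoed in every manifest. No multiple-testing
correction is applied by default (the graph rule uses raw p < 0.05);
Benjamini–Hochberg q-values are available as an annotation flag on the
group comparison and never alter the default outputs.

Group comparison uses Fisher's z = atanh(r), with r clipped to
±(1 − 10⁻¹²) beforehand so degenerate perfect correlations give a large
finite z rather than propagating infinities. The difference statistic is
Z = (z_A − z_B)/√(1/(n_A−3) + 1/(n_B−3)) with p from the standard normal
CDF; it requires n ≥ 4 per group, and pairs failing that are reported
missing with a diagnostic rather than dropped. Averaging member regions
into broader areas (unweighted mean over non-missing members) is an
optional pre-step, off by default, since per-group graphs and cross-group
comparisons need not share it.

## Enhancer screen

PFM counts are smoothed as P(b,j) = (count + pc·bg_b)/(total_j + pc) with
pseudocount pc = 1 distributed by the background (uniform by default),
avoiding −∞ log-odds at zero counts; scores are base-2 log-odds. The scan
threshold is a fraction (default 0.8) of the score range
min + f·(max − min) — a conventional PWM practice adopted because no
published scanning threshold exists for this screen; the fraction is
logged with every run. Score comparisons at the cutoff carry a 10⁻¹²
tolerance to absorb floating-point summation-order differences. Windows
containing non-ACGT characters are skipped; minus-strand hits are reported
in plus-strand coordinates.

Candidate calling requires the motif to lie fully inside the ATAC peak
(the stricter reading of "intersect"), the H3K27ac overlap to be ≥ 1 bp
under half-open arithmetic, and accessibility at or after `min_stage`
under an explicit ordered stage list (PCD11.5 … PD0) — never
lexicographic comparison. "PCD13.5 onwards" is read as *any* qualifying
stage; `require_all_stages=True` gives the stricter reading. The ATAC
interval anchors the candidate; H3K27ac is evidence, not the anchor.

## Conservation

Blocks are restricted to the window by reference coordinates (gap columns
interior to the kept range are retained), concatenated in reference order,
and species missing from a block are padded with gaps — the simple
contract; the gap-vs-unknown distinction is not preserved. Distance is
√(1 − identity) over columns where both species have an unambiguous base,
matching the documented convention of the seqinr identity distance (one
test cross-checks against `dist.alignment` via Rscript). Pairs with zero
comparable columns are missing, not zero.

## Synthetic data

The generators define the study conditions the tests run under.

*Activity.* Values are multivariate normal with the planted per-group
correlation matrix (factorized by symmetric eigendecomposition, so
semi-definite matrices are accepted), scaled to per-region means and
marginal SDs, then floored at 0. The default demo cohort mirrors the
mapping experiment's design: 3 genotypes × 4 animals × 30 regions in 5
areas, within-area r = 0.8 (0.2 in the knockout), means 300–900 cells/mm³
with SD 60 — chosen so the clip fraction stays ≪ 1% (it is recorded on
every table), because clipping distorts planted correlations. All
generators take an explicit seed (default 0) and are byte-deterministic
given it.

*Sequences.* Background is i.i.d. uniform A/C/G/T, making motif-scan
false-positive rates analytically enumerable. Consensi are written in at
planted positions (reverse-complemented on −). To make the expected screen
output exact by construction, the generator then rewrites any background
window within Hamming distance 2 of a planted consensus on either strand
(excluding windows overlapping planted sites) — a pure Hamming criterion
independent of the scanner. For a sharply peaked PWM (the demo matrix uses
97:1:1:1 columns) two mismatches already fall below the 0.8 threshold, so
planted sites are provably the only hits. Ground truth is derived from the
planted design alone, never by running the screen.

*Alignments.* Each non-reference species copies the reference and is
substituted at round(divergence × window) distinct positions, so
reference distances equal √(planted fraction) exactly up to rounding; no
gaps are planted (stitching gap paths are exercised by hand-built
fixtures instead).

What the simulations do not emulate: spatial autocorrelation between
regions beyond the block structure, non-normal (e.g. overdispersed count)
densities, dinucleotide sequence composition, indels and rearrangements in
alignments, and imaging artefacts. Passing tests demonstrate correctness
of the computational contracts under these idealized conditions, not
robustness to real-data pathologies.

## Quantification

Colocalization counts an a-cell if ≥ 1 b-cell lies within an inclusive
Euclidean threshold (default 3 voxels); no one-to-one matching, so the
count is monotone in the threshold. Profile binning treats each sample as
a unit-width segment and splits boundary mass proportionally, conserving
total mass exactly for lengths not divisible by the bin count; bins are
half-open [lo, hi), 0-based, so a point mass at the midpoint of an
even-length profile falls in bin n/2. Percent of input uses the
dilution-adjusted form 100·2^((Ct_input − log2(1/f)) − Ct_IP) with the
input fraction f defaulting to 1 when unknown; values above 100% are
flagged, not clamped.

## Problem sizes and numerical choices

Verification runs use 50 random 6 × 8 tables for the correlation oracle
(tolerances 10⁻¹² on r, 10⁻¹⁰ on p), 2,000 null and 500 planted-difference
replicates for Fisher-z calibration, 100 seeds for parameter recovery
(the recovered estimate is the mean within-block pairwise r̂ over a
4-region block — the block correlation is what the generator plants),
20 × 10 kb sequences at four thresholds for the scan oracle, and 25 seeded
fixtures for screen closure. These sizes give stable statistics while the
whole suite completes in about a minute. Ties at the PWM score cutoff are
resolved inclusively with the 10⁻¹² tolerance above; degenerate inputs
(all-zero profiles, zero DAPI counts, n ≤ 3 comparison groups, non-PSD
correlation targets) raise named errors rather than producing silent NaNs.

## Known limitations

The Fisher-z comparison assumes independent groups and approximate
bivariate normality per pair; at n = 4 its power is minimal and the
normal approximation is rough — the package reports such pairs but the
analyst should treat them descriptively. The permutation p-value option
mitigates the t-transform's normality assumption but not the small-n
resolution limit (n = 4 admits only 24 orderings). The screen does not
model motif clustering, conservation weighting, or quantitative
accessibility; it is a deterministic interval-logic filter by design.
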