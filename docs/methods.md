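# Methods

## Scope and model

`mycnet` reconstructs a two-arm transcription-factor regulatory network from
a two-condition, two-group expression study (reference = wild type, test =
knockdown). The object produced is a `RegulatoryNetwork`:

- **motif arm** — significant genes with ≥ 1 promoter PWM hit,
- **miRNA arm** — significant genes predicted and anti-correlated targets of
  significant miRNAs,
- **overlap** — their intersection, with the overlap fraction reported
  relative to the motif arm (the "fraction of motif-arm genes also under
  miRNA control" reading); the miRNA-arm denominator is emitted as well.

Assembly is a pure function of its three inputs; identical inputs yield
identical networks.

## qPCR preprocessing

Raw TaqMan CT values are censored so that undetected entries (empty, `NA`,
`Undetermined`) and entries above 35 cycles become exactly 35 — the
conventional detection ceiling of the assay; the operation is idempotent.
ΔCT is computed per sample against the U6 small nuclear RNA control row;
greater ΔCT means lower expression. The detection filter keeps miRNAs whose
minimum ΔCT over *all* samples is strictly below 10 cycles; a stricter
per-group variant (`scope="all_groups"`) is available because the scope of
the "minimum" is a genuine modelling choice — the permissive reading is the
default. Copy-number estimation, copies = 10^((40−CT)/3.34)/22, applies to
censored **raw** CT (not ΔCT): the standard-curve calibration behind the
formula is against synthetic spiked miRNA at known raw CT, and its constants
(3.34 cycles per decade ≈ log₂10 amplification efficiency, 22 from ~30 pg
total RNA per cell) only make sense on that scale.

## Differential filtering

With exactly two groups, one-way ANOVA and the equal-variance two-sample
t-test are the same test (F = t²); the implementation uses the t form and
tests verify the F equivalence. Fold change is geometric, from the
difference of log2 group means; for ΔCT input the sign is inverted. Both
reporting cut-offs are strict: |fold| > 2 and p < 0.05; a fold of exactly
2.0 fails. No multiple-testing correction is applied — the combined
fold-change + raw-p filter is the method being modelled. Features with zero
variance in both groups get p = 1 (equal means) or p = 0 (unequal); the
degenerate case is resolved before reporting. Background elimination keeps
features whose maximum over samples exceeds a threshold; absent an explicit
value the 20th percentile of the matrix is used, and the end-to-end driver
passes 4.0 (between the generator's background level 2.0 and its expressed
baseline floor 6.0). Probe→gene collapsing assigns each gene the common
direction of its significant probes; genes with discordant probe directions
are excluded (direction is load-bearing for anti-correlation pairing, so a
majority vote would silently corrupt the arm assignment) and reported.

## Seed-site prediction

The seed is miRNA nucleotides 2–8. Site types on the UTR (DNA, 5′→3′):
8mer = reverse complement of the seed followed by A; 7mer-m8 = reverse
complement of the seed; 7mer-A1 = reverse complement of positions 2–7
followed by A. Where an 8mer spans a locus, its constituent 7mers at the
same locus are not double-reported. The moderate mode adds 7-nt seed
matches with exactly one G:U wobble (miRNA G facing target T, or miRNA U
facing target G), and is a strict superset of the stringent mode — the two
modes emulate the sensitivity contrast between stringent (TargetScan-like)
and moderately stringent (miRanda/miRBase-like) databases, not their exact
historical contents. N never matches. Pairing is membership-based: one pair
per (miRNA, gene) regardless of site multiplicity, with sites kept as
evidence; no context scores, conservation or accessibility.

## PWM scanning

A PWM is a pseudocount-adjusted frequency matrix (default 0.25 per base)
with information vector I(i) = Σ_b f(i,b)·ln(4·f(i,b)) (natural log; the
base only enters through the information weights, and fixing ln keeps
scores deterministic across platforms). The core is the 5 consecutive
positions of maximal summed information (leftmost on ties). Matrix and core
similarity are the information-weighted, min/max-normalized scores in
[0, 1]; the consensus scores exactly 1, the per-position-least-frequent
word exactly 0; N contributes the position minimum. Both strands are
scanned by scoring the forward sequence against the PWM and its reverse
complement (whose core is the mirrored window, set explicitly so strand
symmetry is exact); hits carry the leftmost sense-strand coordinate
relative to the TSS, 0-based half-open, negative upstream. All hits are
reported; overlapping hits are not merged — "distinct sites" means distinct
(position, strand).

The score cutoff is calibrated to an exceedance probability α under an
i.i.d. background: exact enumeration of all 4^L words (with their
background weights, grouped by distinct score so ties cannot leak past α)
for L ≤ 8, seeded Monte-Carlo otherwise. The default working point is
α = 0.01 with a core-score cutoff of 0.75 — α is the reproducible part of
the emulated "best supported" setting; the core cutoff is configurable.
PWMs are read from TRANSFAC flat and JASPAR text formats via Bio.motifs;
the shipped E-box matrix (consensus CCACGTGG, CACGT-centred core) is a
synthetic fixture, not a licensed database matrix. Note the E-box consensus
is reverse-complement palindromic, so a planted consensus legitimately
yields one hit per strand at the same position.

## Enrichment

Per term, p is the upper-tail hypergeometric probability P(X ≥ k) of the
list/term overlap given the annotated universe (all genes on the array);
fold enrichment = (k/n)/(K/N). Reporting keeps p < 0.05 and fold > 2
(strict), ranked by descending count with ties broken by ascending p then
term id. The conservative EASE variant (one hit deducted before the tail)
is available behind a flag; the plain tail is the default because it is the
reproducible statistic. Up- and down-regulated lists are analysed
separately. No GO-graph propagation.

## Synthetic studies

The generator emulates the study design end to end: a 2-replicate (default)
two-group design; per-gene log2 baselines uniform on [6, 12] with a 10%
background fraction near level 2; planted DE genes shifted ±2 log2 units
(default) in the test group with 0.25 log2 units of replicate noise, 20% of
genes carrying two probes with independent noise; miRNA CT baselines on
[22, 28] cycles with a 15% low-expressed fraction near the censoring
ceiling, planted ΔΔCT shifts of −3 cycles (8-fold up) by default, and a U6
control at 20 ± 0.05 cycles; i.i.d. promoter/UTR sequence at GC 0.42 with
planted consensus (or, behind `motif_mutations`, near-consensus) motif
instances on random strands and planted exact 8mer seed sites; ten gene
sets of which one draws 75% of its members from planted DE genes.

Two mechanisms make planted truth *exact* rather than merely likely:

- miRNA seeds are rejection-sampled to be pairwise ≥ 2 mismatches apart and
  free of cross-pattern substring matches inside each other's planted 8mer
  sites, so no planted site can double as a (wobble) hit for another miRNA;
- background sequence is scrubbed: chance occurrences of any simulated
  miRNA's moderate-stringency patterns, and chance PWM windows at or above
  the study's calibrated cutoff on either strand, are resampled from the
  background distribution (planted spans protected) until a scan pass is
  clean, then verified by running the actual predictors.

What the generator does **not** emulate: probe-level intensity physics
(RMA/quantile normalization is upstream of this pipeline's contract),
correlated noise or batch structure, amplification-efficiency variation,
sequence composition beyond i.i.d. nucleotides, conserved or clustered real
miRNA seed families, and chance motif/site occurrences (deliberately, per
the scrubbing above). Passing end-to-end tests therefore demonstrates
correctness of the machinery under the planted model, not recovery rates on
real arrays, where chance sites and correlated noise would add both arms'
false positives back.

## Problem sizes and numerical choices

The end-to-end check uses 200 genes, 40 miRNAs, a 12-gene motif arm, 9-gene
miRNA arm and 4-gene overlap, with generous planted effects chosen by power
analysis (log2 effect 4.0, noise 0.15, ΔΔCT −4, CT noise 0.2, 3
replicates/group) so that the per-feature miss probability is far below
10⁻⁶ and exact truth recovery across ten seeds is the expected outcome, not
a coin flip; the defaults of `SimulationConfig` stay at the milder study
conditions (2 replicates, effect 2.0, noise 0.25, ΔΔCT −3). Unit-test
studies are scaled to 60 genes / 15 miRNAs with 400 + 100 nt promoters.
Monte-Carlo calibration refuses configurations with < 10 expected tail
samples. Score comparisons at cutoffs use ≥ (a hit at exactly the cutoff
counts); DE cut-offs are strictly >/<. All file coordinates are 0-based
half-open; FASTA promoter headers carry `gene|tss_offset|exon_end`.

## Known limitations

Historical database reconstructions (miRBase-era target lists, TargetScan
context scores, licensed TRANSFAC matrices, DAVID's exact statistic) are
out of scope; the two seed-match modes and the local hypergeometric test
capture the *contrasts* those tools contribute to the method. Promoter
scanning covers the supplied region only (no first-intron scanning, no
genome retrieval, no dinucleotide background). The ANOVA is the two-group
special case; designs with more groups are not supported.
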