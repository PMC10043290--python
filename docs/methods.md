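# Methods

This note records the models, conventions and numerical choices behind each
analysis stage, what the synthetic-data generator does and does not emulate,
and the design decisions taken where several defensible options existed.

## Coordinates and interval operations

All genomic coordinates are BED-style 0-based half-open, everywhere
internally; GTF input (1-based closed) is converted on read and on write.
Merging is a per-chromosome sweep over sorted starts; two records union when
they overlap or lie within `gap` bp. Intersection reports, per query record,
whether any subject record shares at least `min_overlap_bp` bp **and** at
least `min_overlap_frac` of the query length; the best partner is the
subject with the largest overlap, ties broken by smaller start (the subject
table is position-sorted, so the first maximum is the tie-break winner).
These semantics match `bedtools intersect` defaults at
`min_overlap_bp = 1, min_overlap_frac = 0`.

Replicate consolidation has two modes. `union_merge` (default) merges the
concatenation of all replicates — peaks merged across samples. The phrase
"replicated peaks" can also be read as reproducibility filtering, so
`intersection` is provided: the merged union clipped to base pairs covered
in every replicate. Which reading is intended is not decidable from the
study description; the default follows the merged-samples reading, and both
are exercised in tests.

## Chromatin state and co-occupancy

A peak is *open* iff it overlaps the (merged) ATAC open-region set by at
least 1 bp; no fraction threshold is imposed by default because none is part
of the method being reproduced — both knobs are exposed. Co-occupancy
`M[a][b]` is the fraction of a's peaks overlapped by ≥ 1 peak of b; it is
row-normalized and asymmetric by construction. Stratified runs restrict the
*row* factor's peaks to a state stratum while keeping the partner's full
peak set (a same-stratum toggle exists); this is the weaker and safer
reading of "co-occupancy at regions of open chromatin". Empty peak sets
report fractions as NA, never as 0.

## Promoter windows and feature annotation

The core-promoter window is TSS − 1000 bp to TSS + 100 bp, strand-aware
(mirrored about the TSS on the minus strand), clipped at position 0. Peaks
are assigned by their midpoint (summit offset when present) to exactly one
feature with priority core_promoter > exon > intron > TTS_flank
(TES ± 1 kb) > intergenic; a midpoint inside several genes' features goes to
the nearest TSS, ties to the lexicographically smaller gene id. Midpoint
assignment forces the feature percentages to partition the peak count,
which any-overlap assignment would not. Upstream tools sometimes split
"promoter/TSS" from "TSS" categories without defining the boundary; this
package deliberately emits a single `core_promoter` category.

## Motif scanning and enrichment

PWMs are position probability matrices with background composition q and a
scoring pseudocount (0.01 of q per cell); JASPAR count matrices are
converted with a pseudocount of 0.8 split by background. The window score is
Σᵢ log₂(pᵢ(bᵢ)/q(bᵢ)); both strands are scanned (the minus strand via the
reverse-complemented score matrix) and windows containing N are skipped.

The default threshold is the smallest score whose per-window
false-positive rate under the background model is ≤ 10⁻⁴. The score
distribution is obtained by column-by-column convolution, merging sums equal
after rounding to 9 decimals — exact for widths ≤ 12 — and to 3 decimals
(a discretized convolution) for wider matrices. A 10⁻⁹ epsilon is subtracted
from the returned threshold so rounding in the convolution can never drop a
window whose true score equals the threshold.

Enrichment of a target region set over a background set is fraction-based:
fold = f_t/f_b where f is the fraction of regions with ≥ 1 hit, matching the
known-motif convention of HOMER-style tools; f_b is floored at 1/(2N_b + 1)
when zero and flagged. The p-value is the exact upper-tail binomial
P(X ≥ k_t | n_t, f_b). Hit densities (hits/kb over all scanned bp, every
starting offset counted once, no greedy masking) are reported alongside, and
differential enrichment between two region sets uses density ratios with a
two-proportion z-test over scanned windows.

The scrambled background is a per-region dinucleotide-preserving shuffle
(Altschul–Erickson Euler-path construction: random last-edge trees with a
connectivity check, then a shuffled Euler walk), one shuffle per region by
default; a mononucleotide mode exists for comparison. Regions shorter than
2 bp fall back to mononucleotide with a logged notice.

## Pseudobulk accessibility and domain calling

Fragments are counted once per region they overlap by ≥ 1 bp; every fragment
of a cluster group contributes to that group's depth whether or not it falls
in a region. The normalized signal is N[r,g] = C[r,g]·10⁶/(D[g]·kb(r)),
invariant under uniform duplication of a group's fragments.

The upstream study does not define "open/closed" thresholds or the exact
differential test, so this module uses an explicit, parameter-recoverable
rule: a region is open in a group iff N ≥ τ_open and closed iff N ≤ τ_closed,
with defaults τ_open = 2× and τ_closed = 0.5× the median of the nonzero
normalized signal across the two groups compared. A *domain 1* call requires
open(reference) ∧ closed(target) **and** a BH-adjusted pooled two-proportion
z-test at q ≤ α (default 0.05); *domain 2* is the converse, making the
caller exactly antisymmetric under swapping the groups. Adjacent same-class
calls within `merge_gap` bp are merged (q of the merged call is the minimum).
Cell clustering is consumed (barcode→cluster table), never computed, and the
reference/target cluster lists are explicit arguments. TSS-level
differential accessibility applies the same test to promoter-window counts
aggregated per gene. The caller itself is deterministic; seeds govern only
simulation.

## DE × binding integration

DE filtering keeps BH-adjusted p < α (strict) and |log2FC| ≥ a configurable
floor; genes with log2FC exactly 0 are excluded with a notice. Gene
identifiers are matched exactly after whitespace/case normalization — no
alias resolution — and DE genes missing from the binding table count as
unbound (logged). "Top 25th percentile" candidate selection ranks by log2
fold-change within the bound + DE subset (the ranking statistic is not
specified upstream; adjusted-p ranking is available), keeps
⌈quantile · n⌉ genes, and breaks ties at the cut by smaller adjusted p then
gene id, making the list invariant to input row order.

## Screen statistics

Folds are reported relative to the control-condition mean, but tests are
two-tailed equal-variance Student's t-tests on the **raw replicate
percentages** (Welch by flag): dividing each replicate by a noisy control
mean would distort the null. A hit requires fold strictly > 1.25 (or
< 1/1.25 for decrease screens) and p < 0.05; no multiple-testing correction
is applied to the hit criterion itself, matching the per-siRNA rule, and a
BH column is emitted for reference. Combination screens enumerate all
subsets (size-then-lexicographic order, 2ⁿ − 1 for n items, guarded at
n ≤ 20) and compare each combination's replicates to the most potent single
hit. Blunting calls flag conditions at ≤ 50% of the reference mean; the
viability gate passes conditions with ≥ 0.7× the control cell count — the
exact cutoff used upstream is unstated, so 0.7 is a documented assumption.
qPCR relative expression is 2^−ΔΔCt.

## Synthetic data: what is emulated, what is not

Every generator is bit-exact given (config, seed). The master seed expands
into per-generator child seeds via `SeedSequence(master, spawn_key=(k,))`
with a fixed index per generator, so regenerating one input never perturbs
the others.

Planted quantities are **realized** quantities wherever the downstream
estimator is deterministic: exactly ⌊frac·n⌉ peaks are placed fully inside
open regions; co-occupancy ρ duplicates exactly ⌊ρ·n_a⌉ of a's peak centers
into b's set; motif carriers receive exact occurrence counts while
non-carrier sequence is rejection-sampled free of consensus matches on
either strand (so planted densities and folds are exactly recoverable by the
scanner rather than inflated by chance matches); DE labels and binding flags
are planted as exact counts (501/235 down/up, 348/112 bound). Sampling noise
enters only where the data-generating process is genuinely stochastic:
fragment counts are Poisson, replicate percentages are truncated normals.

Default scale: 2 chromosomes × 1 Mb, 200 genes, 5,000 peaks per factor,
3,000 cells in 7 clusters with 13% of cells in the target cluster, 500
pseudobulk regions of 500 bp with 100 domain-1 and 60 domain-2 regions at
rate ratio 10, a 5,000-gene DE table, and screen plates of 1,435 / 255 / 200
conditions in quadruplicate. The pseudobulk depth default (expected 1,600
fragments per open region per group) is a power choice: with the target
cluster at 13% of cells, the closed-state Poisson noise must sit well below
the derived τ_closed, which it does because background regions are planted
at 0.4× the open rate, putting the derived thresholds at 0.8× and 0.2× the
open rate — a two-fold margin over the closed rate at ratio 10. The
open-fraction/co-occupancy recovery scenarios use sparse coordinate-only
chromosomes (2 × 500 Mb, tiled open regions): on the 2 Mb pipeline toy,
chance overlap between 20,000 peaks is large and co-occupancy saturates,
which is a property of crowded coordinates, not of the estimator.

Not emulated: read-level data (FASTQ), Tn5 insertion or GC bias, fragment
length distributions, doublets, peak-caller artifacts, gene-expression count
models (the DE table is consumed, as in the pipeline's real use, not fitted),
plate spatial effects. Passing recovery tests therefore demonstrate
correctness of the statistics and bookkeeping on data satisfying the model
assumptions, not robustness to these real-data complications.

## Numerical and degenerate-input conventions

Empty inputs yield defined results (empty merges, NA fractions, zero
summaries) rather than errors unless the operation is meaningless (zero DE
genes, zero target regions). Unsorted interval inputs are auto-sorted with a
logged notice (strict mode available). Ties everywhere break
deterministically (overlap then start; nearest TSS then gene id; adjusted p
then gene id). The pipeline writes all headline numbers to `summary.json`
with sorted keys and fixed rounding, so two runs with identical inputs and
seed are byte-identical; a manifest records parameters and SHA-256 input
checksums.

## Known limitations

* Known-motif enrichment only; no de novo discovery, motif clustering or
  footprinting.
* The exact score-distribution convolution assumes position independence of
  the background (i.i.d. bases); a Markov background would require a
  lattice-specific DP.
* Domain calling operates on a fixed region set (union peaks or tiling);
  it does not re-segment within regions, so domain boundaries are region
  boundaries.
* The two-proportion z-test is a large-count approximation; at very low
  pseudobulk depth an exact test would be preferable.
* Gene identifiers are matched literally; no symbol-alias resolution.
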