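# Methods

This note documents the models implemented in `tpscan`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Coordinates and formats

All intervals are 0-based half-open internally. GFF3 (1-based closed) is
converted on read/write; SAM positions are 1-based; BED6 is native. SAM is
parsed with pysam (aligned span = reference-consuming CIGAR operations);
GFF3 with gffutils. The GFF-type → biotype mapping is an explicit table
(`io_formats.GFF_TYPE_TO_BIOTYPE`); unknown types become `other` with a
warning. Every mapped record contributes to coverage — the upstream
alignment policy allowed multi-mapping and nothing in the counting model
deduplicates; unmapped records are skipped and counted.

## Peak model

Coverage is pooled over all libraries (the feature universe must be a
single, design-wide call for cross-condition set logic to be well defined)
and kept strand-specific. Segmentation takes maximal runs of bases with
depth **strictly greater** than the peak threshold (default 10 reads/base);
retention requires 17 ≤ length ≤ 150 nt and mean depth over the run's own
bases **at or above** 10. The two different operators are intentional: the
run definition is an excess ("more than 10 per base"), the retention filter
an average ("10 or more"). No gap merging is done by default (a single
sub-threshold base splits a run); `merge_gap` exposes merging for users who
want it. Mean coverage is computed over the candidate's own bases, never a
padded window. Peak ids are stable (`TP_<contig>_<strand>_<start>`).

## Genomic-context classification

Classification is against leaf features (exons, introns, UTRs, sRNA genes),
not gene containers, in a fixed cascade: known → nested → overlapping →
intergenic. "Known" is operationalized as reciprocal overlap ≥ 0.8 with an
annotated sRNA-biotype feature on the same strand (both configurable);
containment anywhere beats partial overlap elsewhere because it is the more
specific relation. Orientation comes from the host with the largest
overlap, ties broken by the smallest feature, which makes the choice
deterministic and most specific. rRNA and lincRNA are deliberately not in
the "known sRNA" set: peaks inside them classify as nested, matching how
rRNA-hosted fragments behave in this kind of survey. The interval index is
backed by an interval tree; a brute-force linear scan is kept in the test
suite as an independent oracle.

## Counting

Any-overlap counting (≥ 1 nt, configurable) with ambiguous-read discard,
the default behavior of the standard counting tools this step stands in
for. Unstranded is the library default; the pipeline drivers use stranded
mode because peaks are strand-specific and the simulated protocol is
stranded. Per-sample totals partition exactly into assigned + ambiguous +
no-feature + unassigned-contig, and this is asserted in tests.

## Differential expression

Two deliberately different simplified NB estimators produce the consensus:

* **Method A (Wald).** Counts are normalized by median-of-ratios size
  factors (median over all-positive features of count / feature geometric
  mean; library-size fallback if no such feature exists). log₂FC uses a
  pseudo-count of 0.5 on the group means. The SE comes from the delta
  method under NB variance μ + φμ²; two-sided p from the normal reference.
* **Method B (exact).** Counts are scaled to a common effective library
  size (library size × TMM factor; 30% M-trim, 5% A-trim, factors
  renormalized to geometric mean 1), rounded, and the split of the total
  between group sums is tested conditionally: each group sum is NB with
  dispersion φ/n, and the p-value sums the probabilities of splits no more
  likely than the observed one. With φ = 0 this reduces to a binomial
  split test.

Dispersion: the per-feature moments estimate φ = (s² − m̄)/m̄² (pooled
within-group variance, normalized counts) is shrunk toward a mean-trend
with weight proportional to residual degrees of freedom against 20 prior
degrees of freedom. The trend is the per-bin **mean of the untruncated**
moment estimates: with three replicates per group the estimator's sampling
distribution is strongly right-skewed, so a median — or truncating negative
estimates at zero before averaging — is biased low, which in turn makes the
Wald test anticonservative. With the mean-trend shrinkage the raw method-A
rejection rate under a global NB null (φ = 0.1, 3 vs 3, mean 100) sits at
its nominal level (asserted at 0.05 ∈ [0.03, 0.07] in the tests). Method B
uses a single common dispersion (25%-trimmed mean of the moment estimates
over features with mean ≥ 1).

The consensus rule is a three-gate conjunction per contrast: log₂FC > 1,
BH-adjusted p(A) < 0.05, raw p(B) < 0.05 (down-calls symmetric with
log₂FC < −1 — the downward gate mirrors the stated upward one). BH is
applied within each contrast separately, since each pathogen × generation
is compared only with its own-generation control. These estimators claim
the decision rule's behavior, not numerical identity with any published
package's output.

## Cross-condition logic

Feature identity across contrasts is the peak id from the single pooled
call; per-condition re-calling is rejected because it would make set
membership ill-defined. Membership per direction is exact set algebra over
the four contrasts; shared-all = all four; bacterium-specific = both
generations of exactly one pathogen; generation-specific = exactly one
contrast. Cells partition the DE features and are order-invariant.

## Target screen

The seed is the longest contiguous antiparallel perfect Watson–Crick
complement between the mature miRNA and a candidate transcript, found by
dynamic programming over run lengths, capped at 20 nt, filtered at ≥ 12 nt,
ties broken by smallest target start then smallest miRNA start. G·U wobble
pairs are excluded from the seed by default (strictest reading of perfect
complementarity) and can be enabled.

The seed helix is scored with the Xia et al. (1998) RNA/RNA Watson–Crick
nearest-neighbor parameters: ΔG(T) = Σ stacks (ΔH − T·ΔS) + duplex
initiation (ΔH = 3.61 kcal/mol, ΔS = −1.5 cal/mol/K), evaluated at the
experimental temperature (default 20 °C). No terminal-AU penalty, dangling
ends, or loop terms are included — the score is for the seed helix only,
and hits are *ranked* by (seed length, energy) rather than thresholded,
because no canonical energy cutoff exists; a configurable −10 kcal/mol
"strong" flag is provided as a reporting convenience. Windows containing
G·U cannot be scored (no wobble stack parameters are shipped) and are
reported without an energy. Full transcript sequences are scanned by
default (the biological mechanism of interest is RNAi-like, not
3′UTR-restricted); restricting the candidate set is the caller's choice.

## qPCR ΔΔCt

ΔCt = target Ct − calibrator Ct per sample; replicates are averaged on the
ΔCt scale (standard for the comparative-Ct method; averaging folds instead
would bias the estimate upward); ΔΔCt = mean ΔCt(test) − mean ΔCt(reference);
fold = E^−ΔΔCt with amplification efficiency E fixed at 2 and exposed as a
parameter for sensitivity analysis. Ct values must lie in (0, 45).

## Synthetic data generator

The generator emulates the study design: 3 bacteria × 2 generations × 3
replicate libraries, four pathogen-vs-control contrasts, single-end reads
of 17–36 nt (default 24).

* **Genome/annotation.** ≥ 10 kb contigs hosting two coding genes
  (UTR/exon/intron structure), two miRNA hairpins (pre-miRNA + 22-nt mature),
  an rRNA, tRNA, piRNA, lincRNA and snoRNA, with guaranteed ≥ 1 kb
  intergenic gaps. Pure function of the seed.
* **Coverage semantics.** A planted locus's `target_mean_coverage` is the
  *pooled* per-base depth over all libraries at baseline, split evenly
  across libraries and scaled per library by 2^log₂FC of its condition —
  the same multiplicative model the count-level NB simulator uses. Read
  intervals are clamped to the locus, so pooled coverage is flat across the
  locus and zero outside; start offsets are stratified (even grid, random
  phase) so realized depth stays within about one read of flat per library,
  and per-library read numbers are Poisson. Background reads sit on a
  sparse ~1 kb grid away from loci with pooled depth ≤ 2.
* **Default scenario.** One 50-kb contig, 20 planted loci covering all four
  truth classes and straddling every threshold: coverage below (5×) and
  above (20–300×) the 10× rule, lengths 16/17/150/170 nt around the length
  gates, one zero-coverage locus. One locus is +2 log₂ in all four
  contrasts (the *mir-243* analog, planted on a mature-miRNA annotation),
  one is −2 log₂ in all four (the *mir-70* analog, planted at 300× baseline
  so its repressed pooled coverage still clears the peak threshold), plus
  bacterium-specific, generation-specific and null loci. Depths were chosen
  once so that per-library counts over passing loci are in the tens —
  realistic for a MiSeq-scale sRNA library over a short locus — and are the
  study conditions for all end-to-end tests.
* **Count simulator.** NB(mean = baseline · 2^log₂FC · size factor,
  dispersion φ); φ = 0 degrades to Poisson; deterministic per seed.

What the generator does **not** emulate: real read sequences and base
qualities, sequencing error, adapter content, multi-mapping ambiguity,
miRNA-typical read-length distributions, expression-dependent dispersion
trends, or batch effects. Passing end-to-end tests therefore demonstrates
the correctness of the discovery logic under the declared model, not
robustness to alignment artifacts or library-preparation biases in real
data.

## Problem sizes and numerical conventions

Test and acceptance workloads are sized to run comfortably on one CPU: the
peak-caller oracle uses ~120 random tracks up to 10 kb; the classifier
oracle 1,000 features × 1,000 peaks; the DE null 5,000 features (3 vs 3);
the planted-effect recovery 20 seeds × 400 features; the seed-search oracle
1,000 random pairs. Energies are exact sums over the shipped table
(asserted to 1e-9); BH is checked against a step-by-step implementation;
fold identities to 1e-12. Degenerate inputs have defined behavior: all-zero
features give (log₂FC 0, p 1); an all-zero sample is an error for TMM; an
empty candidate set yields an empty hit list with a warning; empty
classification input is an error for the summary. RNG throughout is
numpy's default generator seeded explicitly; all derived seeds stay below
2³¹.

## Known limitations

* The two DE estimators are simplified by design; they share the decision
  rule, thresholds and normalization lineage of the packages they stand in
  for, but not their exact numerics (no GLM designs, no outlier
  replacement, no independent filtering).
* The exact test enumerates the conditional distribution over the total
  group sum, which is O(total) per feature; for very deep counts a normal
  approximation would be needed.
* The energy model covers Watson–Crick stacks only; wobble-containing
  duplexes are found (when enabled) but not scored.
* Known/novel proportions on synthetic data depend on the planted mix and
  are not expected to reproduce any particular empirical survey's split.
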