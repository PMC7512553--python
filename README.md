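# tpscan

Small-RNA locus discovery and analysis for strand-aware sRNA-seq, built
around the question: *which small RNAs respond to chronic pathogen exposure
in every condition of a multi-pathogen, multi-generation feeding design?*

The motivating biology is intergenerational pathogen-induced diapause in
*C. elegans*: worms fed mild pathogens (*P. aeruginosa* PAO1, *S. enterica*
MST1) for two generations enter the stress-resistant dauer stage, and the
search is for small RNAs — such as the mature microRNA *mir-243-3p* —
induced on **both** pathogens in **both** generations relative to the
*E. coli* OP50 control.

## What the pipeline computes

1. **Transcriptional peaks (TPs).** Alignments from all libraries are pooled
   into strand-specific per-base pileups. A TP is a maximal run of bases
   with depth strictly greater than 10 reads/base, retained when its length
   is 17–150 nt and its mean depth is ≥ 10 (note the deliberate strict
   vs. inclusive operators).
2. **Genomic context.** Each TP is *known* (reciprocal overlap ≥ 0.8, same
   strand, with an annotated sRNA), *partially novel* (nested in or
   overlapping an annotated feature, sense or antisense), or *novel*
   (intergenic).
3. **Counting.** Per-library any-overlap counting over TPs with
   ambiguous-read discard.
4. **Consensus differential expression.** Two simplified
   negative-binomial estimators per pathogen-vs-control contrast — a Wald
   test on median-of-ratios-normalized means with trend-shrunken moments
   dispersion (method A) and a conditional exact test on TMM-equalized
   pseudo-counts with common dispersion (method B). A feature is called
   when log₂FC > 1 (or < −1), BH-adjusted p(A) < 0.05 **and** p(B) < 0.05.
5. **Cross-condition set logic.** Four-set Venn membership per direction
   (PAO1_F1, PAO1_F2, MST1_F1, MST1_F2); shared-all members are the
   universal responders.
6. **Target screen.** Longest contiguous perfect Watson–Crick antiparallel
   complement (seed; cap 20 nt, filter ≥ 12 nt) between a mature miRNA and
   candidate transcripts, scored by nearest-neighbor duplex free energy at
   20 °C.
7. **ΔΔCt.** 2^−ΔΔCt relative expression for calibrator-normalized qPCR.

A synthetic-data module generates every input with known ground truth —
toy genome, annotation, planted sRNA loci with per-contrast log₂ fold
changes (including one universal-up *mir-243* analog and one universal-down
*mir-70* analog), strand-aware read pileups, and NB count matrices — so the
whole pipeline is testable end to end.

## Worked example

The numbered drivers under `analysis/` run the study end to end and write
their tables under `results/analysis/` (regenerated at run time; nothing is
checked in):

```sh
python analysis/01_simulate_study.py --seed 1
python analysis/02_call_peaks.py
python analysis/03_classify_peaks.py
python analysis/05_differential_expression.py   # after 04_quantify.py
python analysis/06_cross_condition.py
```

prints (seed 1):

```
wrote 18 libraries (5593 reads), 20 planted loci, seed=1
called 16 transcriptional peaks from 18 pooled libraries
16 peaks: 12.5% known, 25.0% partially novel, 62.5% novel
PAO1_F1: 2 up ['TP_chrS1_+_4919', 'TP_chrS1_+_807'], 2 down [...]
...
shared-all up: ['TP_chrS1_+_4919']
shared-all down: ['TP_chrS1_-_6132']
```

Of the 20 planted loci, the 16 satisfying the coverage/length rules are
recovered with exact boundaries; the four planted threshold-violators (too
shallow, 16 nt, 170 nt, zero coverage) are correctly absent. The unique
shared-all upregulated peak `TP_chrS1_+_4919` is the planted *mir-243*
analog (a known miRNA locus, +2 log₂ in all four contrasts), and the
shared-all downregulated `TP_chrS1_-_6132` is the planted *mir-70* analog.
`analysis/07_target_screen.py` then screens the induced miRNA against the
downregulated transcripts (1 hit: the planted 14-nt complementary site,
ΔG = −28.8 kcal/mol), and `analysis/08_qpcr_ddct.py` reproduces the
fourfold induction from simulated Ct values (F2: ΔΔCt ≈ −2, fold ≈ 4).

The same stages are exposed as a CLI (`tpscan simulate|call|classify|count|
de|venn|targets|ddct`) for use on external SAM/BED/GFF3 inputs.

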