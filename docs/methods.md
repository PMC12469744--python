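# Methods

`coldreg` asks a narrow question with a deliberately naive toolkit: how much
of a gene's expression response to cold can be predicted from the DNA
sequence immediately around it, across several natural genotypes of a
selfing plant? The package implements the full procedure — motif
enrichment screen, binding-site-count baseline, promoter-sequence CNN with
architecture grid search, and permutation-based significance — together
with a synthetic-data generator that reproduces the statistical structure
of the real task so every stage is testable offline.

## The prediction task

Each record is a (gene, accession) pair. The input is the proximate
regulatory sequence of that gene in that accession's genome; the target is
its differential-expression call between cold and control conditions:
up-regulated DEG vs non-DEG (class labels 0 and 1 respectively), with the
down-regulated contrast run through identical machinery. Class imbalance
is roughly 1:11 DEG:non-DEG, so the headline metric is the area under the
precision-recall curve (prAUC) with the minority DEG class as positive,
accompanied by within-class accuracies and their absolute difference
("class difference"): a model that collapses onto the majority class shows
a large class difference even when raw accuracy looks respectable.

## Window conventions

All windows are oriented gene-5'→3' (minus-strand genes are
reverse-complemented) and anchored on annotated gene coordinates — the TSS
is equated with the annotated gene start, the TTS with the gene end:

| name | anchor | up (bp) | down (bp) | used by |
|---|---|---|---|---|
| `streme_tss` | TSS | 500 | 500 | motif screen |
| `streme_tts` | TTS | 500 | 500 | motif screen |
| `cnn_tss` | TSS | 1000 | 500 | classifier, upstream block |
| `cnn_tts` | TTS | 500 | 1000 | classifier, downstream block |
| `upstream_only` | TSS | 2000 | 0 | promoter-only variant |

The classifier input is the concatenation `cnn_tss` + `cnn_tts`
(L = 3000) or the single 2 kb promoter window (L = 2000). Windows
overhanging a chromosome end are N-padded rather than dropped, so the gene
set is identical across conventions; N one-hot encodes to an all-zero row.
Coordinates are GFF3 1-based inclusive at the interface and 0-based
half-open internally, converted exactly once in `regions`.

## Synthetic data: the stated world

The generator emulates the features of the real data that the analysis
depends on, and nothing more:

- **Reference genome** — i.i.d. uniform ACGT (configurable GC); genes laid
  out with 2 kb clearance on both sides so all window conventions fit and
  never overlap a neighbour's windows.
- **Gene families** — contiguous blocks of gene indices (a shuffled mode
  exists for split-robustness tests). Families are the split unit because
  related genes share promoter sequence; a per-record split would leak.
- **Planted motifs** — 5–15 bp consensi planted Poisson(placement_rate)
  times per gene in the TSS-proximal region (TSS−1000..TSS+500), on either
  strand when `orientation_both_strands`. Occurrences never overlap and are
  recorded, giving exact ground truth for recovery tests.
- **Accessions** — derived from the reference by i.i.d. substitutions at
  `snp_rate` (default 0.005 per bp, a placeholder divergence, not an
  estimate). No indels, so coordinates stay shared, mirroring the
  pseudogenome design of variant-substituted genomes.
- **Labels** — P(up) = σ(β0 + Σm βm·c_gm), where c_gm counts motif m in
  gene g's planting region *of the mutated accession genome*; a SNP that
  destroys an occurrence changes the odds, so genotypes differ in both
  sequence and status (a minimal genotype-by-environment structure).
  Genes not drawn "up" become "down" with an analogous second logit,
  else "non". β0 defaults to logit of the prevalence implied by the 1:11
  target, and the calibration is asserted at n ≥ 10,000 draws.

What a green test on this world does **not** establish: performance on
real promoters (no chromatin, no phylogenetic correlation beyond the
family blocks, no indel or structural variation, uniform base
composition), nor anything about trans regulation.

## Motif screen

A stand-in for a suppression-and-rescan discovery tool with the same
contract. Controls are a uniform down-sample of non-DEG windows to the DEG
set size. Every k-mer (k = 5..12, canonical over both strands) present in
at least 3 windows pooled across both sets is scored by the one-sided
Fisher exact test (= hypergeometric upper tail) on window presence;
e-value = best p × number of candidates scored that round. Because the
candidate filter is label-symmetric, the e-value retains its
family-wise-error reading under the null (asserted empirically: < 5%
of label-shuffled runs emit anything). Emitted motifs have their matches
and Hamming-1 variants masked before rescanning; a round that emits
nothing would repeat identically, so discovery stops there — equivalent to
the three-strikes stop rule for a deterministic scanner. The
hypergeometric tail is computed by a vectorized pmf-recurrence summation
(`hypergeom_logsf_vec`), which matches scipy per-element results to ~1e-12
and keeps full scans fast.

Library matching scores all gapless alignments with ≥ 5 overlapping
columns, both orientations, by mean per-column Pearson correlation of the
frequency vectors (zero-variance columns contribute 0, so a uniform PFM can
never match); significance is the fraction of column-shuffled queries
reaching the observed score.

## Random-forest baseline

Features are per-TF putative-binding-site counts in the 1 kb upstream
window plus a total column (413 columns with the canonical 412-motif
library). The ensemble is scikit-learn's RandomForestClassifier with 500
trees and mtry = 200 (`max_features`). Ranger's `impurity_corrected`
importance has no sklearn equivalent; raw impurity (MDI) importance is
used as the statistic and the Altmann wrapper — refitting under label
permutations and computing p = (b+1)/(n+1) — supplies the bias correction
that mode approximates. prAUC comes from out-of-bag scores (no extra split
consumed; configurable), with label-permutation significance computed the
same way. Under the null these p-values are uniform, which the suite
asserts by a KS test.

## The CNN

No deep-learning framework is assumed: `coldreg.nn` implements Conv1D
(sum of per-tap matmuls), ReLU, max-pool, dense, inverted dropout, a
logit-space binary cross-entropy head and Adam, all float32, verified
against finite-difference gradients. The architecture grammar is
[conv(filters, width) → ReLU → maxpool(width, stride)] × cl → flatten →
[dense(units) → ReLU → dropout] × (dl−1) → 1-unit sigmoid. **Dense-layer
counting includes the output layer**: dl = 3 means two hidden dense layers
plus the sigmoid output, matching how these grids are usually tabulated.

Numerical choices that mattered:

- **Initialization and warmup.** With He initialization, or with full-size
  Adam steps from the first iteration, the uncentered one-hot input
  reliably drove every hidden ReLU negative within an epoch, collapsing
  the network onto a constant logit (training loss pinned at log 2).
  Glorot-uniform initialization plus a linear learning-rate warmup (a
  tenth of the run, capped at 100 steps) removes the failure mode without
  touching the architecture grammar.
- **Model selection.** Validation prAUC is computed after every epoch on
  the *never oversampled* validation set; the weights of the best epoch
  are restored at the end and all reported metrics come from that saved
  model. Training prAUC is reported on the oversampled training set — the
  data as the optimizer saw it.
- **Polarity.** Labels are DEG = 0 / non = 1, so the sigmoid outputs
  P(non); the DEG score is 1 − P(non). prAUC is reported DEG-positive by
  default with the opposite polarity carried alongside
  (`prauc_test_alt`), since the polarity convention is ambiguous in this
  family of analyses.
- **Determinism.** Each grid combination derives its seed from the global
  seed plus a hash of its own hyperparameters, so identical combinations
  give identical records and runs are resumable from per-combination JSON
  checkpoints.

Default grid values (filters {64, 128}, conv width {4, 8}, pool width and
stride {4, 8}, dropout {0.1, 0.25}, dense units {64, 128}, 1–3 conv and
2–3 dense layers, learning rate 1e-4, 50 epochs) reproduce the values
observed across the study's best-model table; the full 1344-point grid is
a configuration artifact, not a constant.

**Selection and significance.** Among grid records with test prAUC ≥ 0.7,
the one with the smallest class difference wins (ties: higher prAUC, then
grid order). A record with test prAUC > 0.8 or < 0.2 is flagged overfit to
one class, with the direction taken from which within-class accuracy is
higher. The selected architecture's label-permutation p shuffles
training+validation labels jointly (test labels untouched), re-oversamples,
retrains, and counts permutations that are at least as good on *both*
criteria (prAUC ≥ observed and class difference ≤ observed), divided by
the number of permutations.

## Report stage

Variant summaries (median/mean test prAUC, class-difference distributions,
overfit fractions split at 0.8/0.2) are regenerated from ModelRecord
tables alone. Distribution comparisons use the two-sample KS test;
motif-count comparisons between correctly and incorrectly predicted genes
use the two-sided Wilcoxon rank-sum test (an all-ties input returns p = 1
with the degenerate case noted). Hyperparameter effect models follow the
canonical formulas `class_diff ~ cl*dl + pl + du + (1|fl)` (Gamma) and
`prauc_test ~ cl*dl*pl + dr + (1|fl)` (binomial), with a beta-family
alternative for the bounded response. statsmodels provides no frequentist
GLMM: the gaussian family uses MixedLM, the binomial family the Bayesian
mixed GLM, and Gamma/beta fall back to fixed-effects-only fits flagged via
the result table's `random_effect` attribute.

## Scaling decisions

Tests and the acceptance script run on one CPU with no network, so
simulated worlds are scaled down (hundreds of genes, 4–16 filter models,
15–50 epochs) and learning rates above the production default are used
where a small model must converge in minutes. Assertion thresholds are
never scaled: spike-learnability requires test prAUC ≥ 0.9, motif recovery
≥ 95% of seeds, null emission < 5%, permutation p exactly 0, family
leakage exactly 0.

## Known limitations

- The motif stand-in discovers exact k-mers (consensus + Hamming-1 mass),
  not refined PWMs; degenerate motifs with two strong variants more than
  one substitution apart surface as separate motifs.
- The Gamma/beta effect models drop the random intercept (no frequentist
  GLMM available), so their p-values ignore between-filter-group
  correlation.
- The CNN engine is CPU-bound numpy; it is meant for desk-scale
  experiments, not for the full grid at production size.
- The generator's SNPs are i.i.d.; linkage and population structure among
  accessions are out of scope.
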