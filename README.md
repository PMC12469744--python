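# coldreg

Predicting cold-responsive differential gene expression from proximate
regulatory DNA sequence, across multiple natural genotypes.

## The problem

Expression responses to the environment are shaped partly by *cis*
regulation: short transcription-factor binding motifs in the sequence
around a gene. `coldreg` implements, as a tested and reusable pipeline,
a procedure for asking how far that proximate sequence alone can predict a
gene's expression response to cold in *Arabidopsis thaliana*-like data —
up-regulated DEG vs non-DEG (and symmetrically down-regulated vs non),
per (gene, accession) pair, across several pseudogenomes that share
coordinates but differ by substitutions.

The pipeline has four analytical stages, plus a synthetic-data generator
so every stage runs and is testable without any external download:

1. **Motif screen** (`coldreg.motifs`) — de novo enriched k-mer discovery
   in DEG regulatory windows against a down-sampled non-DEG control
   (one-sided Fisher exact presence tests, Bonferroni-style e-values,
   masking and rescanning, a stop rule on non-significant rounds), plus
   PFM library matching by column correlation with shuffle significance.
2. **Binding-site baseline** (`coldreg.rf`) — a random forest on per-TF
   binding-site counts in the 1 kb promoter (413 features with the
   canonical 412-motif library; 500 trees, mtry 200), with
   Altmann-permutation importance p-values and label-permutation prAUC
   significance.
3. **Sequence CNN** (`coldreg.cnn`, engine in `coldreg.nn`) — one-hot
   encoded windows (1 kb upstream + 0.5 kb downstream of the TSS
   concatenated with the mirror window at the TTS, L = 3000; or the 2 kb
   promoter alone), gene-family-disjoint 80/20 splits with a 20%
   validation carve-out, minority oversampling to 1:1 in training only,
   50-epoch training with validation-prAUC model saving, a hyperparameter
   grid search, best-model selection (test prAUC ≥ 0.7, minimal
   within-class accuracy difference) and label-permutation significance by
   retraining. A deterministic 5 bp spike (`AAGGG` written over the first
   bases of positive records) serves as the positive control.
4. **Report** (`coldreg.report`) — KS comparisons of metric distributions
   between training variants, overfit accounting (test prAUC > 0.8 or
   < 0.2), Wilcoxon rank-sum motif-count comparisons, and
   generalized-linear hyperparameter effect models
   (`class_diff ~ cl*dl + pl + du + (1|fl)`, Gamma;
   `prauc_test ~ cl*dl*pl + dr + (1|fl)`, binomial).

The key metric throughout is prAUC (area under the precision-recall
curve) with the minority DEG class as positive — the honest choice at the
~1:11 class imbalance this task has — always alongside the two
within-class accuracies and their absolute difference, which expose
models that collapse onto one class.

See `docs/methods.md` for the model details, numerical choices and
limitations.

## Worked example

Simulate a five-accession world in which a planted 10 bp motif raises the
odds of cold up-regulation, then screen for enriched motifs:

```python
import numpy as np
from coldreg import SyntheticConfig, PlantedMotif, simulate_dataset, motifs
from coldreg.regions import extract_window

cfg = SyntheticConfig(
    n_chromosomes=2, chrom_length=850_000, n_genes=280, n_families=56,
    n_accessions=5, snp_rate=0.005,
    planted_motifs=[PlantedMotif("m_up", "ACGTGGCATA", effect=2.0,
                                 placement_rate=0.6)],
    seed=1,
)
ds = simulate_dataset(cfg)

by_id = {a.gene_id: a for a in ds.annotations}
deg, pool = [], []
for lab in ds.labels:
    if lab.status == "down":
        continue
    w = extract_window(ds.genomes[lab.accession_id], by_id[lab.gene_id], "cnn_tss")
    (deg if lab.status == "up" else pool).append(w)
ctrl = motifs.downsample_control(pool, len(deg), seed=1)
for m in motifs.discover_motifs(deg, ctrl, max_motifs=8):
    print(m.id, m.consensus, f"e={m.e_value:.2e}", f"deg_freq={m.deg_frequency:.2f}")
```

On this seed the screen prints the planted driver first, with a decoy
that survives the down-sampled control by chance:

```
motif1 ACGTGGCATA e=2.52e-34 deg_freq=0.82
motif2 GGCAAATA e=3.83e-02 deg_freq=0.10
```

`e` is the best candidate's Fisher p-value times the number of k-mers
scored that round, so `motif1` is unambiguous and `motif2` is marginal —
exactly how a screen against a finite control should behave. Training a
small CNN on the same world goes through `coldreg.datasets`
(`build_records` → `split_by_family` → `oversample` → optionally
`inject_spike`) and `coldreg.SequenceCNN(...).fit(train, val, test)`,
whose results object carries the full metric record and a `summary()`
table.

A command-line interface mirrors these stages
(`coldreg simulate | extract | prepare | motifs | rf-baseline |
train-grid | select | permute | report`); every stage reads and writes
plain text (FASTA, GFF3, TSV, JSON, YAML).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole pipeline from scratch on a freshly simulated world:
genome and label simulation, the motif-enrichment screen (reporting
whether the planted driver is recovered), the TFBS-count random-forest
baseline with permutation significance, a small CNN hyperparameter grid
trained twice (with and without the spike positive control), the KS
comparison between the two grids, best-model selection with its
label-permutation p-value, and the hyperparameter effect models. It
prints each stage's results and writes the JSON report to `--out`.
Runtime is roughly ten minutes on one CPU.
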