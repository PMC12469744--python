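"""Synthetic multi-accession genomes with planted regulatory motifs.

The generator writes a stated world matching the statistical structure the
analysis assumes: a reference genome of i.i.d. background DNA carrying
non-overlapping genes grouped into families; short motifs planted in each
gene's proximal regulatory region at Poisson rates; accession genomes
derived from the reference by independent substitutions (no indels, so
coordinates are shared, as in pseudogenomes); and per-(gene, accession)
regulation labels drawn from a logistic model on the motif counts observed
in that accession's mutated sequence, targeting the ~1:11 DEG:non-DEG
imbalance of the cold-acclimation data.

Because labels are drawn after mutation, accessions differ in both sequence
and status — a minimal genotype-by-environment structure.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np

from . import io
from ._seq import count_occurrences, decode_fast, encode, random_dna, revcomp
from .records import DEGLabel, GeneAnnotation

#: Margin (bp) every gene keeps free on *both* sides so that any window
#: convention (up to 2 kb upstream on either strand) fits on-chromosome
#: without touching a neighbouring gene's windows.
WINDOW_MARGIN = 2000
INTERGENIC_GAP = 200

#: Region (relative to the TSS, gene-oriented) into which motifs are planted;
#: chosen to sit inside every window convention's upstream portion.
PLANT_UP, PLANT_DOWN = 1000, 500


class SizingError(ValueError):
    """Chromosomes too short for the requested genes plus their windows."""


@dataclass(frozen=True)
class PlantedMotif:
    """A short consensus planted at a Poisson rate, nudging the up-logit.

    ``effect`` is the per-occurrence increment to the logit of P(up);
    ``down_effect`` plays the same role for P(down | not up).
    """

    id: str
    consensus: str
    effect: float = 0.0
    placement_rate: float = 1.0
    orientation_both_strands: bool = True
    down_effect: float = 0.0

    def __post_init__(self) -> None:
        if not (5 <= len(self.consensus) <= 15):
            raise ValueError(f"motif {self.id}: consensus length must be 5-15 bp")
        if set(self.consensus) - set("ACGT"):
            raise ValueError(f"motif {self.id}: consensus must be over ACGT")
        if self.placement_rate < 0:
            raise ValueError(f"motif {self.id}: placement_rate must be >= 0")


def _default_ratio() -> float:
    return 1.0 / 11.0


@dataclass
class SyntheticConfig:
    n_chromosomes: int = 2
    chrom_length: int = 600_000
    n_genes: int = 200
    n_families: int = 40
    n_accessions: int = 5
    snp_rate: float = 0.005
    planted_motifs: list[PlantedMotif] = field(default_factory=list)
    baseline_logit: float | None = None  # default: logit of prevalence implied by deg_ratio_target
    deg_ratio_target: float = field(default_factory=_default_ratio)
    baseline_logit_down: float | None = None
    spike_seq: str = "AAGGG"
    gc: float = 0.5
    shuffle_families: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_genes >= self.n_families >= 1) and self.n_genes > 0:
            raise ValueError("need n_genes >= n_families >= 1")
        if not (0 <= self.snp_rate < 1):
            raise ValueError("snp_rate must be in [0, 1)")
        if set(self.spike_seq) - set("ACGT") or not self.spike_seq:
            raise ValueError("spike_seq must be a nonempty ACGT string")
        if not (0 < self.gc < 1):
            raise ValueError("gc must be in (0, 1)")

    @property
    def beta0(self) -> float:
        """Baseline logit: logit of the prevalence implied by deg_ratio_target."""
        if self.baseline_logit is not None:
            return self.baseline_logit
        p = self.deg_ratio_target / (1.0 + self.deg_ratio_target)
        return math.log(p / (1.0 - p))

    @property
    def beta0_down(self) -> float:
        return self.baseline_logit_down if self.baseline_logit_down is not None else self.beta0


@dataclass(frozen=True)
class Placement:
    """Bookkeeping for one planted occurrence (genomic, 0-based start)."""

    gene_id: str
    motif_id: str
    chrom: str
    start0: int
    written: str  # the exact string written into the reference at start0


def generate_reference(
    config: SyntheticConfig,
) -> tuple[dict[str, str], list[GeneAnnotation], list[Placement]]:
    """Build the reference genome, gene annotations and planted-motif records.

    Deterministic for a fixed config (seeds for background, placement and
    motif stages are spawned from ``config.seed``). Genes are laid out
    left-to-right with margins so that every window convention fits; a
    chromosome set too short for the requested genes raises
    :class:`SizingError` naming the deficit.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_bg, rng_place, rng_motif = (np.random.default_rng(s) for s in ss.spawn(3))

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genome_codes = {
        name: encode(random_dna(config.chrom_length, rng_bg, gc=config.gc))
        for name in chrom_names
    }
    if config.n_genes == 0:
        return {n: decode_fast(c) for n, c in genome_codes.items()}, [], []

    families = _family_assignment(config, rng_place)
    annotations: list[GeneAnnotation] = []
    cursor = {name: WINDOW_MARGIN for name in chrom_names}
    ci = 0
    for gi in range(config.n_genes):
        gene_len = int(rng_place.integers(800, 2001))
        placed = False
        for _ in range(len(chrom_names)):
            name = chrom_names[ci]
            start0 = cursor[name]
            end0 = start0 + gene_len  # half-open
            if end0 + WINDOW_MARGIN <= config.chrom_length:
                strand = "+" if rng_place.random() < 0.5 else "-"
                annotations.append(
                    GeneAnnotation(
                        gene_id=f"g{gi:05d}",
                        chrom=name,
                        start=start0 + 1,
                        end=end0,
                        strand=strand,
                        family_id=families[gi],
                    )
                )
                cursor[name] = end0 + 2 * WINDOW_MARGIN + INTERGENIC_GAP
                placed = True
                break
            ci = (ci + 1) % len(chrom_names)
        if not placed:
            deficit = config.n_genes - gi
            raise SizingError(
                f"chromosomes too short: {deficit} of {config.n_genes} genes do not fit "
                f"(need roughly {deficit * (2 * WINDOW_MARGIN + 2000 + INTERGENIC_GAP)} more bp)"
            )

    placements = _plant_motifs(genome_codes, annotations, config, rng_motif)
    genome = {n: decode_fast(c) for n, c in genome_codes.items()}
    return genome, annotations, placements


def _family_assignment(config: SyntheticConfig, rng: np.random.Generator) -> list[str]:
    # contiguous blocks of gene indices by default; optional shuffle mode
    bounds = np.linspace(0, config.n_genes, config.n_families + 1).astype(int)
    fam = np.empty(config.n_genes, dtype=object)
    for f in range(config.n_families):
        fam[bounds[f] : bounds[f + 1]] = f"fam{f:04d}"
    if config.shuffle_families:
        rng.shuffle(fam)
    return list(fam)


def _plant_region(gene: GeneAnnotation) -> tuple[int, int]:
    """Genomic 0-based half-open interval of the planting region (gene-oriented
    TSS-PLANT_UP .. TSS+PLANT_DOWN)."""
    if gene.strand == "+":
        a0 = gene.tss - 1
        return a0 - PLANT_UP, a0 + PLANT_DOWN
    a0 = gene.tss - 1
    return a0 - PLANT_DOWN + 1, a0 + PLANT_UP + 1


def _plant_motifs(
    genome_codes: dict[str, np.ndarray],
    annotations: list[GeneAnnotation],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> list[Placement]:
    placements: list[Placement] = []
    for gene in annotations:
        lo, hi = _plant_region(gene)
        occupied: list[tuple[int, int]] = []
        for motif in config.planted_motifs:
            n_occ = int(rng.poisson(motif.placement_rate))
            L = len(motif.consensus)
            for _ in range(n_occ):
                for _try in range(50):  # rejection-sample a non-overlapping slot
                    pos = int(rng.integers(lo, hi - L + 1))
                    if all(pos + L <= s or pos >= e for s, e in occupied):
                        break
                else:
                    continue  # region saturated; skip this occurrence
                occupied.append((pos, pos + L))
                oriented = motif.consensus if gene.strand == "+" else revcomp(motif.consensus)
                if motif.orientation_both_strands and rng.random() < 0.5:
                    oriented = revcomp(oriented)
                genome_codes[gene.chrom][pos : pos + L] = encode(oriented)
                placements.append(
                    Placement(gene.gene_id, motif.id, gene.chrom, pos, oriented)
                )
    return placements


def derive_accession(
    reference: dict[str, str], snp_rate: float, seed: int
) -> dict[str, str]:
    """Mutate the reference: each base substituted independently with
    probability ``snp_rate`` to a uniformly chosen *different* base.

    Length-preserving (no indels), deterministic per seed. snp_rate=1 is
    rejected so 'accession' always means a perturbation of the reference.
    """
    if not (0 <= snp_rate < 1):
        raise ValueError("snp_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = {}
    for name, seq in reference.items():
        codes = encode(seq).copy()
        mask = rng.random(codes.size) < snp_rate
        idx = np.nonzero(mask)[0]
        shift = rng.integers(1, 4, size=idx.size).astype(np.uint8)
        codes[idx] = (codes[idx] + shift) % 4
        out[name] = decode_fast(codes)
    return out


def _motif_counts(
    gene: GeneAnnotation, genome: dict[str, str], motifs: list[PlantedMotif]
) -> dict[str, int]:
    lo, hi = _plant_region(gene)
    chrom = genome[gene.chrom]
    region = chrom[max(lo, 0) : hi]
    return {
        m.id: count_occurrences(region, m.consensus, both_strands=m.orientation_both_strands)
        for m in motifs
    }


def assign_labels(
    annotations: list[GeneAnnotation],
    config: SyntheticConfig,
    genomes: dict[str, dict[str, str]],
    seed: int | None = None,
) -> list[DEGLabel]:
    """Draw a status per (gene, accession) from the logistic label model.

    P(up) = sigmoid(beta0 + sum_m effect_m * c_gm) with c_gm the occurrence
    count of motif m in the gene's regulatory region *of that accession's
    genome* (so SNPs that destroy a planted occurrence change the odds).
    Among genes not drawn up, P(down) uses beta0_down and the motifs'
    ``down_effect``.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    labels: list[DEGLabel] = []
    for acc_id, genome in genomes.items():
        for gene in annotations:
            counts = _motif_counts(gene, genome, config.planted_motifs)
            z_up = config.beta0 + sum(
                m.effect * counts[m.id] for m in config.planted_motifs
            )
            if rng.random() < _sigmoid(z_up):
                status = "up"
            else:
                z_dn = config.beta0_down + sum(
                    m.down_effect * counts[m.id] for m in config.planted_motifs
                )
                status = "down" if rng.random() < _sigmoid(z_dn) else "non"
            labels.append(DEGLabel(gene.gene_id, acc_id, status))
    return labels


def _sigmoid(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


@dataclass
class SyntheticDataset:
    """Everything one simulation run produced, in memory."""

    config: SyntheticConfig
    reference: dict[str, str]
    genomes: dict[str, dict[str, str]]  # accession -> chrom -> seq
    annotations: list[GeneAnnotation]
    labels: list[DEGLabel]
    placements: list[Placement]

    @property
    def accession_ids(self) -> list[str]:
        return list(self.genomes)


def simulate(config: SyntheticConfig) -> SyntheticDataset:
    """Full generation: reference, accession genomes, labels."""
    reference, annotations, placements = generate_reference(config)
    ss = np.random.SeedSequence([config.seed, 7])
    acc_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_accessions)]
    genomes = {
        f"acc{i + 1}": derive_accession(reference, config.snp_rate, acc_seeds[i])
        for i in range(config.n_accessions)
    }
    labels = assign_labels(annotations, config, genomes)
    return SyntheticDataset(config, reference, genomes, annotations, labels, placements)


def write_outputs(dataset: SyntheticDataset, out_dir: str | os.PathLike) -> list[str]:
    """Write per-accession FASTA, one GFF3, a label TSV and a family TSV.

    Round-trips losslessly through this package's readers.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for acc_id, genome in dataset.genomes.items():
        path = os.path.join(out_dir, f"{acc_id}.fasta")
        io.write_fasta(genome, path)
        written.append(path)
    gff = os.path.join(out_dir, "genes.gff3")
    io.write_gff3(dataset.annotations, gff)
    labels = os.path.join(out_dir, "labels.tsv")
    io.write_labels(dataset.labels, labels)
    fams = os.path.join(out_dir, "families.tsv")
    io.write_families(dataset.annotations, fams)
    return written + [gff, labels, fams]
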