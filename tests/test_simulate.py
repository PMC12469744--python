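"""Generator contracts: determinism, label-model calibration, SNP statistics,
planted-motif conservation and file round-trips."""

import math

import numpy as np
import pytest

from coldreg import io
from coldreg._seq import count_occurrences, find_occurrences, revcomp
from coldreg.simulate import (
    PlantedMotif,
    SizingError,
    SyntheticConfig,
    _plant_region,
    assign_labels,
    derive_accession,
    generate_reference,
    simulate,
    write_outputs,
)


class TestGenerateReference:
    def test_empty_gene_set(self):
        cfg = SyntheticConfig(n_genes=0, n_chromosomes=1, chrom_length=10_000, seed=1)
        genome, annotations, placements = generate_reference(cfg)
        assert annotations == [] and placements == []
        assert set(genome) == {"chr1"} and len(genome["chr1"]) == 10_000

    def test_deterministic_outputs(self, tmp_path):
        cfg = SyntheticConfig(
            n_genes=20, n_families=4, n_accessions=2, chrom_length=100_000,
            planted_motifs=[PlantedMotif("m", "ACGTACGT", placement_rate=1.0)], seed=1,
        )
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_outputs(simulate(cfg), d1)
        write_outputs(simulate(cfg), d2)
        for f in sorted(p.name for p in d1.iterdir()):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f

    def test_genes_and_windows_non_overlapping(self, small_dataset):
        by_chrom = {}
        for a in small_dataset.annotations:
            by_chrom.setdefault(a.chrom, []).append(a)
        for genes in by_chrom.values():
            genes.sort(key=lambda g: g.start)
            for g1, g2 in zip(genes, genes[1:]):
                # 2 kb margin on either side keeps all window conventions disjoint
                assert g2.start - g1.end > 2 * 2000

    def test_sizing_error_names_deficit(self):
        cfg = SyntheticConfig(n_genes=50, n_families=5, n_chromosomes=1,
                              chrom_length=30_000, seed=0)
        with pytest.raises(SizingError, match="genes do not fit"):
            generate_reference(cfg)

    def test_planted_occurrence_mean_matches_rate(self):
        # oracle: regex count of the consensus on the emitted sequence
        motif = PlantedMotif("m", "ACGGATTCCGTA", placement_rate=2.0)  # 12-mer: chance hits negligible
        cfg = SyntheticConfig(
            n_genes=500, n_families=50, n_chromosomes=2, chrom_length=1_600_000,
            planted_motifs=[motif], seed=5,
        )
        genome, annotations, placements = generate_reference(cfg)
        counts = []
        for g in annotations:
            lo, hi = _plant_region(g)
            counts.append(count_occurrences(genome[g.chrom][lo:hi], motif.consensus))
        mean = np.mean(counts)
        se = math.sqrt(2.0 / len(counts))
        assert abs(mean - 2.0) < 3 * se

    def test_planted_positions_conserved_on_reference(self):
        # every recorded placement is literally present at its coordinates
        motif = PlantedMotif("m", "ACGGATTCCGTA", placement_rate=1.5)
        cfg = SyntheticConfig(n_genes=100, n_families=10, chrom_length=400_000,
                              planted_motifs=[motif], seed=9)
        genome, _, placements = generate_reference(cfg)
        assert placements
        for p in placements:
            seen = genome[p.chrom][p.start0 : p.start0 + len(p.written)]
            assert seen == p.written
            assert p.written in (motif.consensus, revcomp(motif.consensus))


class TestDeriveAccession:
    def test_zero_rate_is_identity(self, toy_genome):
        assert derive_accession(toy_genome, 0.0, seed=3) == toy_genome

    def test_mismatch_count_matches_rate(self):
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1_000_000)])
        mutated = derive_accession({"c": seq}, 0.01, seed=1)["c"]
        # oracle: Hamming distance on the output
        mismatches = sum(a != b for a, b in zip(seq, mutated))
        assert abs(mismatches - 10_000) < 3 * math.sqrt(10_000 * 0.99)

    def test_full_rate_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            derive_accession(toy_genome, 1.0, seed=0)

    def test_deterministic_per_seed(self, toy_genome):
        a = derive_accession(toy_genome, 0.01, seed=11)
        b = derive_accession(toy_genome, 0.01, seed=11)
        c = derive_accession(toy_genome, 0.01, seed=12)
        assert a == b
        assert a != c


class TestAssignLabels:
    def _labels(self, cfg):
        genome, annotations, _ = generate_reference(cfg)
        genomes = {f"acc{i}": genome for i in range(cfg.n_accessions)}
        return assign_labels(annotations, cfg, genomes)

    def test_baseline_prevalence_calibrated(self):
        # with zero effects the up-fraction is Binomial(n, 1/12); check the
        # closed-form 99% interval at n = 12,000 (gene, accession) draws
        cfg = SyntheticConfig(
            n_genes=2400, n_families=240, n_accessions=5, n_chromosomes=2,
            chrom_length=6_800_000, snp_rate=0.0, seed=2,
        )
        labels = self._labels(cfg)
        assert len(labels) == 12_000
        p = 1.0 / 12.0
        frac = sum(l.status == "up" for l in labels) / len(labels)
        half = 2.576 * math.sqrt(p * (1 - p) / len(labels))
        assert abs(frac - p) < half

    def test_saturating_effect_forces_up(self):
        motif = PlantedMotif("m", "ACGGATTCCGTA", effect=50.0, placement_rate=1.0)
        cfg = SyntheticConfig(n_genes=100, n_families=10, n_accessions=1,
                              chrom_length=400_000, snp_rate=0.0,
                              planted_motifs=[motif], seed=3)
        genome, annotations, _ = generate_reference(cfg)
        labels = assign_labels(annotations, cfg, {"acc1": genome})
        by_gene = {l.gene_id: l.status for l in labels}
        with_motif = [
            g for g in annotations
            if count_occurrences(genome[g.chrom][slice(*_plant_region(g))], motif.consensus)
        ]
        assert with_motif
        assert all(by_gene[g.gene_id] == "up" for g in with_motif)

    def test_degenerate_baseline_gives_no_up(self):
        cfg = SyntheticConfig(n_genes=50, n_families=5, n_accessions=2,
                              chrom_length=200_000, baseline_logit=-50.0,
                              baseline_logit_down=-50.0, seed=4)
        labels = self._labels(cfg)
        assert all(l.status == "non" for l in labels)

    def test_snps_can_flip_label_odds(self, small_dataset):
        # labels drawn after mutation: the same gene may differ across accessions
        status = {}
        for l in small_dataset.labels:
            status.setdefault(l.gene_id, set()).add(l.status)
        assert any(len(s) > 1 for s in status.values())


class TestWriteOutputs:
    def test_file_set_and_round_trip(self, small_dataset, tmp_path):
        files = write_outputs(small_dataset, tmp_path)
        assert len(files) == 3 + 1 + 2  # 3 accession FASTAs + GFF3 + 2 TSVs
        back = io.read_gff3(tmp_path / "genes.gff3")
        assert back == small_dataset.annotations
        labels = io.read_labels(tmp_path / "labels.tsv")
        assert labels == small_dataset.labels
        for acc, genome in small_dataset.genomes.items():
            assert io.read_fasta(tmp_path / f"{acc}.fasta") == genome

    def test_fasta_wrapped_at_60(self, small_dataset, tmp_path):
        write_outputs(small_dataset, tmp_path)
        with open(tmp_path / "acc1.fasta") as fh:
            body = [l.rstrip("\n") for l in fh if not l.startswith(">")]
        assert max(len(l) for l in body) == 60

    def test_empty_label_table(self, tmp_path):
        path = tmp_path / "labels.tsv"
        io.write_labels([], path)
        assert io.read_labels(path) == []
        assert path.read_text().splitlines()[0] == "gene_id\taccession\tstatus"

    def test_planted_motifs_recoverable_from_files(self, tmp_path):
        # with snp_rate=0 every placement survives in every accession FASTA
        motif = PlantedMotif("m", "ACGGATTCCGTA", placement_rate=1.0)
        cfg = SyntheticConfig(n_genes=40, n_families=8, n_accessions=2,
                              chrom_length=200_000, snp_rate=0.0,
                              planted_motifs=[motif], seed=6)
        ds = simulate(cfg)
        write_outputs(ds, tmp_path)
        genome = io.read_fasta(tmp_path / "acc1.fasta")
        for p in ds.placements:
            hits = find_occurrences(genome[p.chrom], motif.consensus)
            assert any(abs(h - p.start0) < 1 for h in hits)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SyntheticConfig(n_genes=3, n_families=5)
    with pytest.raises(ValueError):
        SyntheticConfig(snp_rate=1.0)
    with pytest.raises(ValueError):
        SyntheticConfig(spike_seq="AAXGG")
    with pytest.raises(ValueError):
        PlantedMotif("m", "ACG")  # too short
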