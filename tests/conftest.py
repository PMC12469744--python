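import numpy as np
import pytest

from coldreg import datasets
from coldreg.records import GeneAnnotation
from coldreg.regions import RegulatoryInput
from coldreg.simulate import PlantedMotif, SyntheticConfig, simulate


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic world: 2 chromosomes, 60 genes in 12
    families, 3 accessions, one planted motif that raises the up-odds."""
    cfg = SyntheticConfig(
        n_chromosomes=2,
        chrom_length=200_000,
        n_genes=60,
        n_families=12,
        n_accessions=3,
        snp_rate=0.002,
        planted_motifs=[
            PlantedMotif("m_up", "ACGTGGCA", effect=1.0, placement_rate=1.0)
        ],
        seed=42,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def toy_genome():
    """One deterministic 12 kb chromosome for window-arithmetic fixtures."""
    rng = np.random.default_rng(7)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 12_000)])
    return {"chr1": seq}


def make_record(gene_id, family_id, label, seq="ACGT" * 5, accession="acc1"):
    """A lightweight record for split/oversample tests (sequence content is
    irrelevant there)."""
    return RegulatoryInput(
        gene_id=gene_id,
        accession_id=accession,
        conventions=("cnn_tss",),
        sequences=(seq,),
        family_id=family_id,
        label=label,
    )


@pytest.fixture
def imbalanced_records():
    """1:11 class imbalance across 24 families, mimicking the DEG ratio."""
    records = []
    for i in range(1200):
        fam = f"f{i % 24:03d}"
        label = datasets.DEG_CLASS if i % 12 == 0 else datasets.NON_CLASS
        records.append(make_record(f"g{i:04d}", fam, label))
    return records


def gene(gene_id="g1", chrom="chr1", start=5001, end=6000, strand="+", family="fam1"):
    return GeneAnnotation(gene_id, chrom, start, end, strand, family)
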