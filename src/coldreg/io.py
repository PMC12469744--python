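"""Readers and writers for the pipeline's on-disk formats.

FASTA goes through Biopython (wrapped at 60 columns on write; indexed
access via pyfaidx). Gene annotations are GFF3 with feature type "gene"
and ``ID=``/``family=`` attributes. Label and family tables are plain TSV.
"""

from __future__ import annotations

import os
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import DEGLabel, GeneAnnotation

LABEL_COLUMNS = ["gene_id", "accession", "status"]


def write_fasta(genome: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def open_indexed_fasta(path: str | os.PathLike):
    """Random-access FASTA handle (pyfaidx); usable wherever a genome mapping is."""
    import pyfaidx

    return pyfaidx.Fasta(str(path), sequence_always_upper=True)


def write_gff3(annotations: list[GeneAnnotation], path: str | os.PathLike,
               source: str = "coldreg") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            attrs = f"ID={a.gene_id};family={a.family_id}"
            fh.write(
                f"{a.chrom}\t{source}\tgene\t{a.start}\t{a.end}\t.\t{a.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | os.PathLike) -> list[GeneAnnotation]:
    out: list[GeneAnnotation] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            kv = dict(item.split("=", 1) for item in attrs.split(";") if "=" in item)
            out.append(
                GeneAnnotation(
                    gene_id=kv["ID"],
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    family_id=kv.get("family", kv["ID"]),
                )
            )
    return out


def write_labels(labels: list[DEGLabel], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(l.gene_id, l.accession_id, l.status) for l in labels], columns=LABEL_COLUMNS
    )
    df.to_csv(path, sep="\t", index=False)


def read_labels(path: str | os.PathLike) -> list[DEGLabel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    return [
        DEGLabel(gene_id=r.gene_id, accession_id=r.accession, status=r.status)
        for r in df.itertuples()
    ]


def write_families(annotations: list[GeneAnnotation], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(a.gene_id, a.family_id) for a in annotations], columns=["gene_id", "family_id"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_families(path: str | os.PathLike) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["gene_id"], df["family_id"]))
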