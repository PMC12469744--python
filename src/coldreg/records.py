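"""Shared domain records: gene annotations and DEG labels.

Coordinates follow GFF3 conventions at the boundary (1-based, inclusive);
all internal slicing converts to 0-based half-open exactly once, in
:mod:`coldreg.regions`.
"""

from __future__ import annotations

from dataclasses import dataclass

STATUSES = ("up", "down", "non")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene's location on a named chromosome plus its family membership."""

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # "+" or "-"
    family_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.family_id:
            raise ValueError(f"{self.gene_id}: empty family_id")

    @property
    def tss(self) -> int:
        """Transcription start site (1-based): gene start on +, gene end on -."""
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        """Transcription termination site (1-based)."""
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class DEGLabel:
    """Regulation status of one gene in one accession: up, down or non."""

    gene_id: str
    accession_id: str
    status: str

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"status must be one of {STATUSES}, got {self.status!r}")
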