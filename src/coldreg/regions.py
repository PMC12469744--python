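"""Strand-aware regulatory window extraction and one-hot encoding.

Window conventions (all in bp relative to the anchor, in the gene's 5'->3'
orientation):

========== ====== ====== ========================================
name       up_bp  down_bp anchor
========== ====== ====== ========================================
streme_tss   500    500  TSS  (motif screen, upstream block)
streme_tts   500    500  TTS  (motif screen, downstream block)
cnn_tss     1000    500  TSS  (classifier input, upstream block)
cnn_tts      500   1000  TTS  (classifier input, downstream block)
upstream_only 2000    0  TSS  (promoter-only classifier input)
========== ====== ====== ========================================

Coordinates: annotations are GFF3 1-based inclusive; slicing here is
0-based half-open. Windows on minus-strand genes are reverse-complemented
so "upstream" is always leftmost in the returned string. Overhang past a
chromosome end is filled with N (edge genes are padded, never dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import revcomp
from .records import GeneAnnotation


@dataclass(frozen=True)
class WindowConvention:
    name: str
    anchor: str  # "tss" or "tts"
    up_bp: int
    down_bp: int

    @property
    def length(self) -> int:
        return self.up_bp + self.down_bp


CONVENTIONS: dict[str, WindowConvention] = {
    c.name: c
    for c in (
        WindowConvention("streme_tss", "tss", 500, 500),
        WindowConvention("streme_tts", "tts", 500, 500),
        WindowConvention("cnn_tss", "tss", 1000, 500),
        WindowConvention("cnn_tts", "tts", 500, 1000),
        WindowConvention("upstream_only", "tss", 2000, 0),
    )
}

MODES = {
    "both_regions": ("cnn_tss", "cnn_tts"),  # concatenated, L = 3000
    "upstream_only": ("upstream_only",),  # L = 2000
}


class EncodingError(ValueError):
    pass


def get_convention(convention: str | WindowConvention) -> WindowConvention:
    if isinstance(convention, WindowConvention):
        return convention
    try:
        return CONVENTIONS[convention]
    except KeyError:
        raise ValueError(
            f"unknown window convention {convention!r}; known: {sorted(CONVENTIONS)}"
        ) from None


def extract_window(genome, gene: GeneAnnotation, convention: str | WindowConvention) -> str:
    """Extract the convention's window for one gene, oriented 5'->3'.

    ``genome`` is any mapping chrom -> sequence (dict of str, or a
    pyfaidx.Fasta). The anchor base itself falls in the downstream part of
    the window: a + strand gene with start s under (up, down) yields the
    1-based genomic interval [s-up, s+down-1].
    """
    conv = get_convention(convention)
    if gene.chrom not in genome:
        raise KeyError(f"chromosome {gene.chrom!r} not present in genome")
    chrom = genome[gene.chrom]
    clen = len(chrom)
    anchor = gene.tss if conv.anchor == "tss" else gene.tts
    a0 = anchor - 1  # 0-based index of the anchor base
    if gene.strand == "+":
        lo, hi = a0 - conv.up_bp, a0 + conv.down_bp
    else:
        lo, hi = a0 - conv.down_bp + 1, a0 + conv.up_bp + 1
    lo2, hi2 = min(max(lo, 0), clen), min(max(hi, 0), clen)
    left_pad = max(0, -lo)
    right_pad = (hi - lo) - left_pad - (hi2 - lo2)
    seq = str(chrom[lo2:hi2]).upper()
    seq = "N" * left_pad + seq + "N" * right_pad
    if gene.strand == "-":
        seq = revcomp(seq)
    assert len(seq) == conv.length
    return seq


_ONEHOT_ROWS = {
    "A": (1.0, 0.0, 0.0, 0.0),
    "C": (0.0, 1.0, 0.0, 0.0),
    "G": (0.0, 0.0, 1.0, 0.0),
    "T": (0.0, 0.0, 0.0, 1.0),
    "N": (0.0, 0.0, 0.0, 0.0),
}
_OH_TABLE = np.zeros((256, 4), dtype=np.float32)
for _b, _row in _ONEHOT_ROWS.items():
    _OH_TABLE[ord(_b)] = _row
    _OH_TABLE[ord(_b.lower())] = _row
_VALID = np.zeros(256, dtype=bool)
for _b in "ACGTNacgtn":
    _VALID[ord(_b)] = True


def one_hot(seq: str) -> np.ndarray:
    """L x 4 one-hot matrix, channel order A,C,G,T; N rows are all-zero."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    bad = np.nonzero(~_VALID[raw])[0]
    if bad.size:
        i = int(bad[0])
        raise EncodingError(f"invalid base {seq[i]!r} at position {i} (0-based)")
    return _OH_TABLE[raw]


def decode_one_hot(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot`; all-zero rows decode to N."""
    mat = np.asarray(mat)
    idx = mat.argmax(axis=1)
    chars = np.array(list("ACGT"))[idx]
    chars[mat.sum(axis=1) == 0] = "N"
    return "".join(chars)


@dataclass
class RegulatoryInput:
    """One (gene, accession) record: the extracted window sequence(s) and label.

    ``sequences`` holds one string per convention in ``conventions``; the
    one-hot encoding of their concatenation is built lazily and cached.
    label is the binary target (0 = DEG of the contrast, 1 = non-DEG).
    """

    gene_id: str
    accession_id: str
    conventions: tuple[str, ...]
    sequences: tuple[str, ...]
    family_id: str
    label: int | None = None
    _onehot: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def sequence(self) -> str:
        return "".join(self.sequences)

    @property
    def onehot(self) -> np.ndarray:
        if self._onehot is None:
            self._onehot = one_hot(self.sequence)
        return self._onehot

    @property
    def length(self) -> int:
        return sum(get_convention(c).length for c in self.conventions)

    def with_sequences(self, sequences: tuple[str, ...]) -> "RegulatoryInput":
        return replace(self, sequences=sequences, _onehot=None)


def build_input(
    gene: GeneAnnotation,
    accession_id: str,
    genome,
    mode: str = "both_regions",
    label: int | None = None,
) -> RegulatoryInput:
    """Assemble the classifier input for one gene in one accession.

    mode "both_regions": cnn_tss window then cnn_tts window (L = 3000);
    mode "upstream_only": the single 2 kb promoter window (L = 2000).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; known: {sorted(MODES)}")
    convs = MODES[mode]
    seqs = tuple(extract_window(genome, gene, c) for c in convs)
    return RegulatoryInput(
        gene_id=gene.gene_id,
        accession_id=accession_id,
        conventions=convs,
        sequences=seqs,
        family_id=gene.family_id,
        label=label,
    )
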