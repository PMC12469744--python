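"""Low-level DNA string helpers shared across modules.

Sequences are plain upper-case Python strings over {A,C,G,T,N}; numeric
work uses uint8 codes A=0, C=1, G=2, T=3, N=4 so that valid bases fit in
two bits (k-mer hashing relies on this).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving N."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a sequence to uint8 codes (A,C,G,T -> 0..3, anything else -> 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def random_dna(n: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    """i.i.d. background sequence with the given GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=n, p=p).astype(np.uint8)
    return decode_fast(codes)


def decode_fast(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def find_occurrences(seq: str, pattern: str, both_strands: bool = True) -> list[int]:
    """0-based start positions of (possibly overlapping) exact matches.

    Reverse-strand matches are reported at the position of the match on
    the forward string (i.e. where the reverse complement of ``pattern``
    occurs).
    """
    hits = _scan(seq, pattern)
    if both_strands:
        rc = revcomp(pattern)
        if rc != pattern:
            hits = sorted(set(hits) | set(_scan(seq, rc)))
    return hits


def _scan(seq: str, pattern: str) -> list[int]:
    out = []
    i = seq.find(pattern)
    while i != -1:
        out.append(i)
        i = seq.find(pattern, i + 1)
    return out


def count_occurrences(seq: str, pattern: str, both_strands: bool = True) -> int:
    return len(find_occurrences(seq, pattern, both_strands))


def hamming_neighbors(seq: str) -> list[str]:
    """All sequences at Hamming distance exactly 1."""
    out = []
    for i, base in enumerate(seq):
        for b in BASES:
            if b != base:
                out.append(seq[:i] + b + seq[i + 1 :])
    return out


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
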