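"""De novo k-mer motif enrichment against a down-sampled control.

A desk-scale stand-in for a suppression-and-rescan motif discovery tool:
every candidate k-mer (k in a configurable range, both strands, canonical
form) is scored by the one-sided Fisher exact test on window
presence/absence in DEG vs control windows; the best candidate's e-value
is its p-value times the number of candidates scored that round. Emitted
motifs have their matches (and Hamming-distance-1 variants) masked before
the next round; discovery stops after a run of non-significant rounds.

Candidate k-mers are pre-filtered by *pooled* presence count, which is
independent of the labels, so the Bonferroni-style e-value remains valid
under the null. Because scanning is deterministic, a round that emits
nothing leaves the windows unchanged and every subsequent round would be
identical; the stop rule therefore short-circuits after the first failing
round, which is equivalent to requiring ``stop_after`` failures in a row.

Library matching mirrors a column-correlation motif comparison: all
gapless alignments of at least ``min_overlap`` columns, both orientations,
scored by the mean per-column Pearson correlation, with significance from
column-shuffles of the query.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

from ._seq import encode, hamming_neighbors, revcomp


@dataclass
class Motif:
    id: str
    consensus: str
    pfm: np.ndarray  # L x 4, columns over A,C,G,T summing to 1 per position
    p_value: float
    e_value: float
    deg_frequency: float  # fraction of DEG windows containing >= 1 match

    @property
    def length(self) -> int:
        return len(self.consensus)


@dataclass
class EnrichmentResult:
    motif: Motif
    a: int  # DEG windows with a match
    b: int  # DEG windows without
    c: int  # control windows with a match
    d: int  # control windows without
    p_value: float
    significant: bool


def downsample_control(
    non_deg_windows: list[str], n: int, seed: int = 0
) -> list[str]:
    """Uniform sample of ``n`` control windows without replacement."""
    if n > len(non_deg_windows):
        raise ValueError(
            f"cannot sample {n} windows from a pool of {len(non_deg_windows)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(non_deg_windows), size=n, replace=False)
    return [non_deg_windows[i] for i in idx]


def _window_kmer_sets(windows: list[str], k: int, both_strands: bool) -> list[np.ndarray]:
    """Per-window sorted arrays of distinct (canonical) k-mer hashes.

    Hash = base-4 value of the k-mer (A=0..T=3); k-mers containing N are
    skipped. Canonical hash = min(hash, revcomp hash) when both strands.
    """
    out = []
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    rc_powers = 4 ** np.arange(k, dtype=np.int64)
    for w in windows:
        codes = encode(w).astype(np.int64)
        if codes.size < k:
            out.append(np.empty(0, dtype=np.int64))
            continue
        win = np.lib.stride_tricks.sliding_window_view(codes, k)
        valid = (win < 4).all(axis=1)
        win = win[valid]
        h = win @ powers
        if both_strands:
            h_rc = (3 - win) @ rc_powers
            h = np.minimum(h, h_rc)
        out.append(np.unique(h))
    return out


def _presence_counts(kmer_sets: list[np.ndarray], size: int) -> np.ndarray:
    if not kmer_sets:
        return np.zeros(size, dtype=np.int64)
    allh = np.concatenate(kmer_sets) if kmer_sets else np.empty(0, dtype=np.int64)
    return np.bincount(allh, minlength=size)


def _decode_hash(h: int, k: int) -> str:
    return "".join("ACGT"[(h >> (2 * (k - 1 - i))) & 3] for i in range(k))


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_logsf_vec(a, N, K, n, tol: float = 1e-16) -> np.ndarray:
    """log P(X >= a) for X ~ Hypergeometric(N, K, n), vectorized over a and K.

    Exact tail sum via the pmf ratio recurrence, accumulated in log space;
    the loop stops once the next term can no longer move the sum by ``tol``
    relatively. Orders of magnitude faster than per-element scipy calls for
    the k-mer scan, and agrees with it to ~1e-12.
    """
    a = np.asarray(a, dtype=np.int64)
    K = np.broadcast_to(np.asarray(K, dtype=np.int64), a.shape).copy()
    upper = np.minimum(K, n)
    x = a.copy()
    # log pmf at the starting point; empty tails (a > upper) give -inf
    with np.errstate(invalid="ignore"):
        logterm = np.where(
            x > upper,
            -np.inf,
            _log_comb(K, np.minimum(x, K))
            + _log_comb(N - K, np.clip(n - x, 0, None))
            - _log_comb(N, n),
        )
    logsum = logterm.copy()
    active = (x < upper) & np.isfinite(logterm)
    log_tol = np.log(tol)
    while active.any():
        xa = x[active]
        Ka = K[active]
        ratio = (
            np.log(Ka - xa)
            + np.log(n - xa)
            - np.log(xa + 1)
            - np.log(N - Ka - n + xa + 1)
        )
        logterm[active] = logterm[active] + ratio
        logsum[active] = np.logaddexp(logsum[active], logterm[active])
        x[active] += 1
        active = active & (x < upper)
        active[active] = (logterm[active] - logsum[active]) > log_tol
    return np.minimum(logsum, 0.0)


def fisher_enrichment_p(a: int, n_deg: int, c: int, n_ctrl: int):
    """One-sided Fisher exact (= hypergeometric upper tail) for enrichment.

    Returns (p, logp); logp is usable for ranking when p underflows.
    """
    N, K, n = n_deg + n_ctrl, a + c, n_deg
    p = float(stats.hypergeom.sf(a - 1, N, K, n))
    logp = float(stats.hypergeom.logsf(a - 1, N, K, n))
    return p, logp


def discover_motifs(
    deg_windows: list[str],
    control_windows: list[str],
    k_range: range = range(5, 13),
    alpha: float = 0.05,
    stop_after: int = 3,
    both_strands: bool = True,
    min_presence: int = 3,
    max_motifs: int = 50,
    seed: int = 0,
) -> list[Motif]:
    """Iterative enriched-k-mer discovery with masking and an e-value stop rule.

    ``seed`` is accepted for interface symmetry; the scan itself is
    deterministic.
    """
    if not deg_windows or not control_windows:
        raise ValueError("both window sets must be nonempty")
    deg = [w.upper() for w in deg_windows]
    ctrl = [w.upper() for w in control_windows]
    motifs: list[Motif] = []
    failures = 0
    while failures < stop_after and len(motifs) < max_motifs:
        best = _best_candidate(deg, ctrl, k_range, both_strands, min_presence)
        if best is None:
            break
        consensus, p, logp, n_candidates, a = best
        e_value = float(np.exp(min(logp + np.log(n_candidates), 700.0)))
        if e_value > alpha:
            failures += 1
            # nothing was masked, so the next round would be identical;
            # the remaining failures are forgone conclusions
            break
        pfm, matched_deg = _pfm_from_matches(deg, consensus, both_strands)
        motifs.append(
            Motif(
                id=f"motif{len(motifs) + 1}",
                consensus=consensus,
                pfm=pfm,
                p_value=p,
                e_value=e_value,
                deg_frequency=matched_deg / len(deg),
            )
        )
        deg = [_mask(w, consensus, both_strands) for w in deg]
        ctrl = [_mask(w, consensus, both_strands) for w in ctrl]
        failures = 0
    motifs.sort(key=lambda m: m.e_value)
    return motifs


def _best_candidate(deg, ctrl, k_range, both_strands, min_presence):
    """Scan all k, return (consensus, p, logp, n_candidates, a) of the best
    candidate, or None when nothing passes the presence filter."""
    best = None
    n_candidates = 0
    per_k = []
    for k in k_range:
        deg_sets = _window_kmer_sets(deg, k, both_strands)
        ctrl_sets = _window_kmer_sets(ctrl, k, both_strands)
        size = 4**k
        a_counts = _presence_counts(deg_sets, size)
        c_counts = _presence_counts(ctrl_sets, size)
        pooled = a_counts + c_counts
        cand = np.nonzero(pooled >= min_presence)[0]
        n_candidates += cand.size
        if cand.size:
            per_k.append((k, cand, a_counts[cand], c_counts[cand]))
    if n_candidates == 0:
        return None
    n_deg, n_ctrl = len(deg), len(ctrl)
    for k, cand, a_arr, c_arr in per_k:
        logp = hypergeom_logsf_vec(a_arr, n_deg + n_ctrl, a_arr + c_arr, n_deg)
        i = int(np.argmin(logp))
        entry = (float(logp[i]), -k, int(cand[i]))
        if best is None or entry < best[0]:
            consensus = _decode_hash(int(cand[i]), k)
            best = (entry, consensus, float(np.exp(logp[i])), float(logp[i]), int(a_arr[i]))
    _, consensus, p, logp_best, a = best
    return consensus, p, logp_best, n_candidates, a


def _match_variants(consensus: str, both_strands: bool) -> list[str]:
    variants = [consensus] + hamming_neighbors(consensus)
    if both_strands:
        variants += [revcomp(v) for v in variants]
    return sorted(set(variants))


def _pfm_from_matches(windows, consensus, both_strands):
    """PFM from all occurrences of the consensus and its Hamming-1 variants
    (overlapping-variant merging); returns (pfm, n_windows_with_exact_match)."""
    variants = _match_variants(consensus, both_strands)
    k = len(consensus)
    counts = np.zeros((k, 4), dtype=float)
    exact = {consensus}
    if both_strands:
        exact.add(revcomp(consensus))
    n_matched = 0
    for w in windows:
        hit = False
        for v in variants:
            i = w.find(v)
            while i != -1:
                inst = v if v in exact or _fwd(v, consensus) else revcomp(v)
                counts += _onehot_counts(inst)
                if v in exact:
                    hit = True
                i = w.find(v, i + 1)
        if hit:
            n_matched += 1
    if counts.sum() == 0:
        counts += _onehot_counts(consensus)
    pfm = counts / counts.sum(axis=1, keepdims=True)
    return pfm, n_matched


def _fwd(variant: str, consensus: str) -> bool:
    """True when the variant is closer to the forward consensus than to its RC."""
    d_f = sum(a != b for a, b in zip(variant, consensus))
    d_r = sum(a != b for a, b in zip(variant, revcomp(consensus)))
    return d_f <= d_r


def _onehot_counts(seq: str) -> np.ndarray:
    out = np.zeros((len(seq), 4), dtype=float)
    for i, b in enumerate(seq):
        out[i, "ACGT".index(b)] = 1.0
    return out


def _mask(window: str, consensus: str, both_strands: bool) -> str:
    for v in _match_variants(consensus, both_strands):
        while v in window:  # loop catches overlapping occurrences
            window = window.replace(v, "N" * len(v))
    return window


def enrichment_table(
    motif: Motif, deg_windows: list[str], control_windows: list[str],
    alpha: float = 0.05, both_strands: bool = True,
) -> EnrichmentResult:
    """Recompute the 2x2 presence table and Fisher p for a motif's consensus."""
    pats = {motif.consensus}
    if both_strands:
        pats.add(revcomp(motif.consensus))
    a = sum(any(p in w.upper() for p in pats) for w in deg_windows)
    c = sum(any(p in w.upper() for p in pats) for w in control_windows)
    b, d = len(deg_windows) - a, len(control_windows) - c
    p, _ = fisher_enrichment_p(a, len(deg_windows), c, len(control_windows))
    return EnrichmentResult(motif, a, b, c, d, p, p < alpha)


def count_motifs_per_gene(
    windows: dict[str, list[str]], motifs: list[Motif], both_strands: bool = True
) -> dict[str, int]:
    """Per gene: how many distinct discovered motifs match any of its windows."""
    if not motifs:
        raise ValueError("motif list must be nonempty")
    out = {}
    for gene, wins in windows.items():
        wins = [wins] if isinstance(wins, str) else wins
        n = 0
        for m in motifs:
            pats = {m.consensus}
            if both_strands:
                pats.add(revcomp(m.consensus))
            if any(p in w.upper() for w in wins for p in pats):
                n += 1
        out[gene] = n
    return out


# ---------------------------------------------------------------------------
# library matching


def _rc_pfm(pfm: np.ndarray) -> np.ndarray:
    return pfm[::-1, ::-1]


def _column_correlation(q: np.ndarray, t: np.ndarray) -> float:
    """Mean per-column Pearson correlation between two equal-length PFM blocks;
    zero-variance columns contribute 0."""
    qc = q - q.mean(axis=1, keepdims=True)
    tc = t - t.mean(axis=1, keepdims=True)
    num = (qc * tc).sum(axis=1)
    den = np.sqrt((qc**2).sum(axis=1) * (tc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return float(r.mean())


def _best_alignment_score(query: np.ndarray, target: np.ndarray, min_overlap: int):
    """Best mean-column-correlation over all gapless offsets and orientations."""
    best = (-np.inf, 0, "+")
    for orient, tgt in (("+", target), ("-", _rc_pfm(target))):
        Lq, Lt = len(query), len(tgt)
        for offset in range(-(Lq - min_overlap), Lt - min_overlap + 1):
            qs, qe = max(0, -offset), min(Lq, Lt - offset)
            if qe - qs < min_overlap:
                continue
            score = _column_correlation(query[qs:qe], tgt[qs + offset : qe + offset])
            if score > best[0]:
                best = (score, offset, orient)
    return best


@dataclass
class LibraryMatch:
    library_id: str
    score: float
    offset: int
    orientation: str
    p_value: float


def match_to_library(
    query: Motif,
    library: list[tuple[str, np.ndarray]],
    min_overlap: int = 5,
    n_shuffles: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[LibraryMatch]:
    """Match a discovered motif against a PFM library.

    p-value = fraction of column-shuffled queries whose best alignment score
    reaches the observed one; matches with p < alpha are returned, best
    score first.
    """
    if query.length < min_overlap:
        raise ValueError(
            f"query length {query.length} shorter than min_overlap {min_overlap}"
        )
    rng = np.random.default_rng(seed)
    qpfm = np.asarray(query.pfm, dtype=float)
    shuffles = [qpfm[rng.permutation(len(qpfm))] for _ in range(n_shuffles)]
    out = []
    for lib_id, tpfm in library:
        tpfm = np.asarray(tpfm, dtype=float)
        obs, offset, orient = _best_alignment_score(qpfm, tpfm, min_overlap)
        null = np.array(
            [_best_alignment_score(s, tpfm, min_overlap)[0] for s in shuffles]
        )
        p = float((null >= obs - 1e-12).mean())
        if p < alpha:
            out.append(LibraryMatch(lib_id, obs, offset, orient, p))
    out.sort(key=lambda m: (-m.score, m.p_value))
    return out


# ---------------------------------------------------------------------------
# MEME minimal motif format


def write_meme(motifs: list[Motif], path: str, background=None) -> None:
    bg = background or [0.25, 0.25, 0.25, 0.25]
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\n"
            f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n"
        )
        for m in motifs:
            fh.write(f"MOTIF {m.id} {m.consensus}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.length} "
                f"nsites= 20 E= {m.e_value:.3g}\n"
            )
            for row in m.pfm:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path: str) -> list[tuple[str, np.ndarray]]:
    """Read a minimal MEME motif file into (id, PFM) pairs (Biopython parser)."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        record = bio_motifs.parse(fh, "minimal")
    out = []
    for m in record:
        pwm = np.array([[m.pwm[b][i] for b in "ACGT"] for i in range(m.length)])
        out.append((m.name, pwm))
    return out
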