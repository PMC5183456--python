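"""Sequence-level primitives.

Global protein alignment (Needleman–Wunsch with affine gaps, Gotoh algorithm)
and the four donor–recipient genome similarity measures used in the barrier
analysis:

* ``S_gs``  — Jaccard index of canonical 20 bp segments of the two genomes,
* ``S_cds`` — the same, restricted to segments overlapping protein-coding
  regions by at least 10% of the segment length,
* ``S_gc``  — 100 − |%GC_a − %GC_b|,
* ``D_cu``  — Euclidean distance between vectors of relative synonymous codon
  frequencies per amino acid (59 degenerate sense codons).

A gap of length L costs ``gap_open + L * gap_extend``. The default scoring is
an identity matrix (match 1, mismatch 0) so that the alignment maximizes the
number of identical aligned positions subject to gap costs; percent identity is
identical positions over alignment columns. A BLOSUM62 similarity mode is
available for real (indel-containing) protein inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib
import numpy as np
from Bio.Align import substitution_matrices

from .genetic_code import (
    AA_ALPHABET,
    DEGENERATE_CODONS,
    DEGENERATE_INDEX,
    SYNONYMOUS_GROUPS,
    codon_indices,
    CODONS,
)

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5

_NEG = -1e30

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class SimilarityProfile:
    """Pairwise genome similarity measures; all symmetric in the two genomes."""

    s_gs: float
    s_cds: float | None
    s_gc: float
    d_cu: float
    habitat_shared: bool

    def __post_init__(self):
        if not (0.0 <= self.s_gs <= 1.0):
            raise ValueError("s_gs outside [0, 1]")
        if self.s_cds is not None and not (0.0 <= self.s_cds <= 1.0):
            raise ValueError("s_cds outside [0, 1]")
        if not (0.0 <= self.s_gc <= 100.0):
            raise ValueError("s_gc outside [0, 100]")
        if self.d_cu < 0:
            raise ValueError("d_cu negative")


# --------------------------------------------------------------------------
# Global alignment
# --------------------------------------------------------------------------

def _score_matrix(a: str, b: str, mode: str) -> np.ndarray:
    """Pairwise residue scores, shape (len(a), len(b))."""
    if mode == "identity":
        av = np.frombuffer(a.encode(), dtype=np.uint8)
        bv = np.frombuffer(b.encode(), dtype=np.uint8)
        return (av[:, None] == bv[None, :]).astype(float)
    if mode == "blosum62":
        alpha = _BLOSUM62.alphabet
        idx = {c: i for i, c in enumerate(alpha)}
        # non-standard residues score as strong mismatch
        ai = np.array([idx.get(c, idx["*"]) for c in a])
        bi = np.array([idx.get(c, idx["*"]) for c in b])
        m = np.asarray(_BLOSUM62)
        return m[np.ix_(ai, bi)]
    raise ValueError(f"unknown scoring mode {mode!r}")


def global_align(
    a: str,
    b: str,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    mode: str = "identity",
) -> tuple[float, str, str]:
    """Gotoh global alignment. Returns (score, aligned_a, aligned_b).

    Ties in the traceback are broken deterministically (match state first,
    then vertical, then horizontal gap state).
    """
    if not a or not b:
        raise ValueError("empty sequence")
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    s = _score_matrix(a, b, mode)

    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in b (vertical, consumes a)
    Y = np.full((n + 1, m + 1), _NEG)  # gap in a (horizontal, consumes b)
    M[0, 0] = 0.0
    j = np.arange(1, m + 1)
    Y[0, 1:] = -(gap_open + j * gap_extend)
    i = np.arange(1, n + 1)
    X[1:, 0] = -(gap_open + i * gap_extend)

    karr = np.arange(m + 1)
    for r in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[r - 1], X[r - 1]), Y[r - 1])
        M[r, 1:] = prev_best[:-1] + s[r - 1]
        X[r, 1:] = np.maximum(
            np.maximum(M[r - 1, 1:], Y[r - 1, 1:]) - gap_open - gap_extend,
            X[r - 1, 1:] - gap_extend,
        )
        X[r, 0] = -(gap_open + r * gap_extend)
        # Y within-row: Y[r, j] = max_{k<j} (A[k] - gap_open - (j-k) extend)
        A = np.maximum(M[r], X[r])
        P = np.maximum.accumulate(A + karr * gap_extend)
        Y[r, 1:] = P[:-1] - gap_open - (karr[1:] + 0.0) * gap_extend

    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    ri, ci = n, m
    tol = 1e-9
    vals = (M[ri, ci], X[ri, ci], Y[ri, ci])
    score = max(vals)
    state = int(np.argmax([v >= score - tol for v in vals]))  # M, X, Y priority
    while ri > 0 or ci > 0:
        if state == 0:  # M: consumed a[ri-1], b[ci-1]
            out_a.append(a[ri - 1])
            out_b.append(b[ci - 1])
            target = M[ri, ci] - s[ri - 1, ci - 1]
            ri, ci = ri - 1, ci - 1
            if ri == 0 and ci == 0:
                break
            cand = (M[ri, ci], X[ri, ci], Y[ri, ci])
            state = next(k for k in range(3) if cand[k] >= target - tol)
        elif state == 1:  # X: consumed a[ri-1] against a gap
            out_a.append(a[ri - 1])
            out_b.append("-")
            v = X[ri, ci]
            ri -= 1
            if M[ri, ci] - gap_open - gap_extend >= v - tol:
                state = 0
            elif X[ri, ci] - gap_extend >= v - tol:
                state = 1
            else:
                state = 2
        else:  # Y: consumed b[ci-1] against a gap
            out_a.append("-")
            out_b.append(b[ci - 1])
            v = Y[ri, ci]
            ci -= 1
            if M[ri, ci] - gap_open - gap_extend >= v - tol:
                state = 0
            elif X[ri, ci] - gap_open - gap_extend >= v - tol:
                state = 1
            else:
                state = 2
    return float(score), "".join(reversed(out_a)), "".join(reversed(out_b))


def global_align_identity(
    a: str,
    b: str,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    mode: str = "identity",
) -> float:
    """Percent identity of the global alignment, in [0, 100].

    Identity is the number of identically matched aligned positions divided by
    the total alignment length (gap columns included), times 100. In
    ``blosum62`` mode the alignment is scored with BLOSUM62 but identity is
    still counted as identical residues.
    """
    _, aln_a, aln_b = global_align(a, b, gap_open, gap_extend, mode)
    matches = sum(1 for x, y in zip(aln_a, aln_b) if x == y and x != "-")
    return 100.0 * matches / len(aln_a)


def identity_upper_bound(a: str, b: str, max_edits: int = -1) -> float:
    """Cheap upper bound on global percent identity via edit distance (edlib).

    Any alignment's mismatch+gap column count is at least the edit distance
    ``d``, and its match count is at most ``min(len)``, so percent identity can
    never exceed ``100 * min_len / (min_len + d)``. Used only to skip hopeless
    pairs in all-vs-all searches; every pair whose bound reaches the decision
    threshold is re-scored with the exact aligner. With ``max_edits`` set,
    edlib abandons early and pairs beyond it report a bound of 0.
    """
    mn = min(len(a), len(b))
    d = edlib.align(a, b, mode="NW", task="distance", k=max_edits)["editDistance"]
    if d < 0:  # distance exceeds max_edits
        return 0.0
    return 100.0 * mn / (mn + d)


def max_edits_for_identity(threshold: float, min_len: int) -> int:
    """Largest edit distance compatible with ``identity >= threshold`` (in %)
    for sequences whose shorter member has ``min_len`` residues."""
    return math.floor(min_len * (100.0 - threshold) / threshold)


# --------------------------------------------------------------------------
# k-mer genome similarity
# --------------------------------------------------------------------------

_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.int64)
    for base, idx in zip("ACGT", range(4)):
        out[arr == ord(base)] = idx
    if np.any(out == 255):
        raise ValueError("non-ACGT nucleotide in genome sequence")
    return out


def _kmer_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """Canonical (strand-collapsed) integer codes of all overlapping k-mers."""
    n = enc.size
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(enc, k)
    fwd = win @ powers
    rc_enc = (3 - enc)[::-1]
    rwin = np.lib.stride_tricks.sliding_window_view(rc_enc, k)
    rev = (rwin @ powers)[::-1]  # rev[i] = code of revcomp of window at i
    return np.minimum(fwd, rev)


def kmer_set(seq: str, k: int = 20) -> np.ndarray:
    """Sorted unique canonical k-mer codes of a genome."""
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    return np.unique(_kmer_codes(_encode(seq), k))


def jaccard_from_sets(a: np.ndarray, b: np.ndarray) -> float | None:
    """Jaccard of two sorted unique code arrays; None when both are empty."""
    if a.size == 0 and b.size == 0:
        return None
    inter = np.intersect1d(a, b, assume_unique=True).size
    union = a.size + b.size - inter
    return inter / union


def kmer_jaccard(genome_a: str, genome_b: str, k: int = 20) -> float:
    """Jaccard index of canonical overlapping k-mer sets of two genomes."""
    val = jaccard_from_sets(kmer_set(genome_a, k), kmer_set(genome_b, k))
    assert val is not None
    return val


def cds_kmer_set(
    seq: str,
    cds_intervals: list[tuple[int, int]],
    k: int = 20,
    min_overlap_fraction: float = 0.1,
) -> np.ndarray:
    """Canonical k-mer codes restricted to segments overlapping a CDS.

    ``cds_intervals`` are 0-based half-open. A k-mer starting at position i is
    kept when at least ``ceil(min_overlap_fraction * k)`` of its bases fall
    inside some CDS interval.
    """
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    enc = _encode(seq)
    n = enc.size
    cov = np.zeros(n + 1, dtype=np.int32)
    for s, e in cds_intervals:
        if s < 0 or e > n or s >= e:
            raise ValueError(f"CDS interval ({s}, {e}) outside genome bounds")
        cov[s] += 1
        cov[e] -= 1
    covered = (np.cumsum(cov)[:-1] > 0).astype(np.int32)
    csum = np.concatenate([[0], np.cumsum(covered)])
    overlap = csum[k:] - csum[:-k]  # covered bases per k-mer window
    need = math.ceil(min_overlap_fraction * k)
    codes = _kmer_codes(enc, k)
    return np.unique(codes[overlap >= need])


def cds_restricted_jaccard(
    genome_a: str,
    genome_b: str,
    cds_a: list[tuple[int, int]],
    cds_b: list[tuple[int, int]],
    k: int = 20,
    min_overlap_fraction: float = 0.1,
) -> float | None:
    """CDS-restricted k-mer Jaccard (``S_cds``); None when both sets are empty
    (no qualifying coding segments on either genome — the undefined 0/0 case).

    Each genome's k-mer set is filtered by its own CDS annotation.
    """
    sa = cds_kmer_set(genome_a, cds_a, k, min_overlap_fraction)
    sb = cds_kmer_set(genome_b, cds_b, k, min_overlap_fraction)
    return jaccard_from_sets(sa, sb)


# --------------------------------------------------------------------------
# GC and codon usage
# --------------------------------------------------------------------------

def gc_percent(seq: str) -> float:
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    return 100.0 * gc / len(seq)


def gc_similarity(gc_a: float, gc_b: float) -> float:
    """GC-content similarity: 100 − |%GC_a − %GC_b|."""
    for v in (gc_a, gc_b):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"GC percentage {v} outside [0, 100]")
    return 100.0 - abs(gc_a - gc_b)


def codon_usage_profile(cds_sequences: list[str]) -> np.ndarray:
    """Relative synonymous codon frequencies per amino acid.

    Returns a 59-vector over degenerate sense codons; within each amino acid's
    synonymous group the entries sum to 1. Amino acids absent from the input
    contribute uniform frequencies so that distances remain defined.
    """
    counts = np.zeros(len(DEGENERATE_CODONS))
    for seq in cds_sequences:
        for ci in codon_indices(seq):
            codon = CODONS[ci]
            j = DEGENERATE_INDEX.get(codon)
            if j is not None:
                counts[j] += 1
    profile = np.zeros_like(counts)
    for _aa, group in SYNONYMOUS_GROUPS.items():
        idx = [DEGENERATE_INDEX[c] for c in group]
        total = counts[idx].sum()
        if total > 0:
            profile[idx] = counts[idx] / total
        else:
            profile[idx] = 1.0 / len(idx)
    return profile


def validate_usage_profile(profile: np.ndarray) -> None:
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (len(DEGENERATE_CODONS),):
        raise ValueError(
            f"profile must have {len(DEGENERATE_CODONS)} entries, got {profile.shape}"
        )
    if np.any(profile < 0):
        raise ValueError("negative codon frequency")
    for aa, group in SYNONYMOUS_GROUPS.items():
        idx = [DEGENERATE_INDEX[c] for c in group]
        s = profile[idx].sum()
        if not math.isclose(s, 1.0, abs_tol=1e-6):
            raise ValueError(f"synonymous frequencies for {aa} sum to {s}, not 1")


def codon_usage_distance(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """Euclidean distance between two relative codon-usage vectors (``D_cu``)."""
    validate_usage_profile(profile_a)
    validate_usage_profile(profile_b)
    diff = np.asarray(profile_a, dtype=float) - np.asarray(profile_b, dtype=float)
    return float(np.sqrt(np.sum(diff * diff)))
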