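"""Standard genetic code tables used by the simulator and the selection analyses.

Everything here is precomputed at import time from Biopython's standard codon
table (NCBI table 1): codon <-> amino-acid maps, per-codon synonymous /
non-synonymous site counts, single-mutation classification tables, and
pathway-averaged substitution counts for codon pairs (Nei–Gojobori style).

Site-counting convention: mutations creating a stop codon are excluded and the
remaining single-nucleotide changes at a position are renormalized so that each
codon position contributes exactly one site. This keeps the simulator's
substitution planting and the NG86 estimator on the same opportunity scale.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_table = CodonTable.unambiguous_dna_by_id[1]

CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
STOP_CODONS = frozenset(_table.stop_codons)
CODON_TO_AA = {c: ("*" if c in STOP_CODONS else _table.forward_table[c]) for c in CODONS}

AA_ALPHABET = sorted(set(_table.forward_table.values()))

# Codons participating in codon-usage vectors: degenerate sense codons only
# (Met=ATG and Trp=TGG are non-degenerate; stops excluded). 59 codons.
SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]
_aa_counts: dict[str, int] = {}
for _c in SENSE_CODONS:
    _aa_counts[CODON_TO_AA[_c]] = _aa_counts.get(CODON_TO_AA[_c], 0) + 1
DEGENERATE_CODONS = [c for c in SENSE_CODONS if _aa_counts[CODON_TO_AA[c]] > 1]
DEGENERATE_INDEX = {c: i for i, c in enumerate(DEGENERATE_CODONS)}

# Synonymous codon groups per amino acid (degenerate amino acids only).
SYNONYMOUS_GROUPS: dict[str, list[str]] = {}
for _c in DEGENERATE_CODONS:
    SYNONYMOUS_GROUPS.setdefault(CODON_TO_AA[_c], []).append(_c)

# --- single-mutation classification -----------------------------------------
# MUT_CLASS[codon_idx, pos, base] for the codon obtained by setting `pos` to
# `base`:  0 = synonymous, 1 = non-synonymous, 2 = creates a stop codon (or the
# source codon is a stop), 3 = no change (base equals current one).
MUT_CLASS = np.full((64, 3, 4), 3, dtype=np.int8)
for ci, codon in enumerate(CODONS):
    for pos in range(3):
        for bi, base in enumerate(BASES):
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if codon in STOP_CODONS or alt in STOP_CODONS:
                MUT_CLASS[ci, pos, bi] = 2
            elif CODON_TO_AA[alt] == CODON_TO_AA[codon]:
                MUT_CLASS[ci, pos, bi] = 0
            else:
                MUT_CLASS[ci, pos, bi] = 1

# --- NG86 site counts ---------------------------------------------------------
# SYN_SITES[ci], NONSYN_SITES[ci]: per-codon counts summing to 3 for sense
# codons (stop-creating changes excluded, per-position renormalization).
SYN_SITES = np.zeros(64)
NONSYN_SITES = np.zeros(64)
for ci, codon in enumerate(CODONS):
    if codon in STOP_CODONS:
        continue
    for pos in range(3):
        cls = MUT_CLASS[ci, pos]
        n_syn = int(np.sum(cls == 0))
        n_non = int(np.sum(cls == 1))
        valid = n_syn + n_non
        if valid == 0:  # cannot happen with the standard code
            continue
        SYN_SITES[ci] += n_syn / valid
        NONSYN_SITES[ci] += n_non / valid


def _pathway_counts(a: str, b: str) -> tuple[float, float]:
    """Average synonymous/non-synonymous differences between codons `a` and `b`
    over all shortest mutational pathways, skipping pathways through stops."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur = a
        syn = non = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if not blocked:
            results.append((syn, non))
    if not results:
        # all pathways pass through a stop; fall back to counting stop steps
        # as non-synonymous over all orders
        for order in itertools.permutations(diff):
            cur = a
            syn = non = 0.0
            for pos in order:
                nxt = cur[:pos] + b[pos] + cur[pos + 1:]
                if nxt in STOP_CODONS or CODON_TO_AA[nxt] != CODON_TO_AA[cur]:
                    non += 1
                else:
                    syn += 1
                cur = nxt
            results.append((syn, non))
    arr = np.asarray(results)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())


# PAIR_SYN[ai, bi], PAIR_NONSYN[ai, bi]: pathway-averaged differences.
PAIR_SYN = np.zeros((64, 64))
PAIR_NONSYN = np.zeros((64, 64))
for _ai, _a in enumerate(CODONS):
    if _a in STOP_CODONS:
        continue
    for _bi, _b in enumerate(CODONS):
        if _b in STOP_CODONS:
            continue
        s, n = _pathway_counts(_a, _b)
        PAIR_SYN[_ai, _bi] = s
        PAIR_NONSYN[_ai, _bi] = n


def encode_nt(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 array (A,C,G,T -> 0..3)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    if np.any(out == 255):
        bad = chr(int(arr[np.argmax(out == 255)]))
        raise ValueError(f"non-ACGT nucleotide {bad!r} in sequence")
    return out


def decode_nt(arr: np.ndarray) -> str:
    return "".join(BASES[i] for i in arr)


def codon_indices(seq: str) -> np.ndarray:
    """Codon index array for an in-frame nucleotide sequence."""
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    enc = encode_nt(seq)
    return (enc[0::3].astype(np.int64) * 16 + enc[1::3] * 4 + enc[2::3])


def translate_codons(seq: str) -> str:
    return "".join(CODON_TO_AA[CODONS[i]] for i in codon_indices(seq))
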