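import itertools
import math

import numpy as np
import pytest

from phagelgt import selection
from phagelgt.genetic_code import CODON_TO_AA, STOP_CODONS
from phagelgt.seqsim import codon_usage_profile
from phagelgt.simulate import mutate_transferred_gene

from conftest import random_cds


BASES = "ACGT"


# --------------------------------------------------------------------------
# Independent NG86 oracle: explicit per-codon site counting and exhaustive
# enumeration of shortest mutational pathways between codon pairs
# --------------------------------------------------------------------------

def oracle_sites(codon: str) -> tuple[float, float]:
    syn = 0.0
    for pos in range(3):
        changes = [codon[:pos] + b + codon[pos + 1:] for b in BASES if b != codon[pos]]
        valid = [c for c in changes if c not in STOP_CODONS]
        if not valid:
            continue
        frac = sum(CODON_TO_AA[c] == CODON_TO_AA[codon] for c in valid) / len(valid)
        syn += frac
    return syn, 3.0 - syn


def oracle_pathway_diffs(a: str, b: str) -> tuple[float, float]:
    """Average synonymous/non-synonymous difference counts over every pathway
    of single-base steps between codons a and b; pathways through stop codons
    are discarded. Each pathway permutes the set of differing positions."""
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(positions):
        cur, syn, non, ok = a, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            totals.append((syn, non))
    if not totals:
        return 0.0, 0.0
    return (sum(t[0] for t in totals) / len(totals),
            sum(t[1] for t in totals) / len(totals))


def oracle_dnds(seq_a: str, seq_b: str) -> tuple[float, float]:
    cod_a = [seq_a[i:i + 3] for i in range(0, len(seq_a), 3)]
    cod_b = [seq_b[i:i + 3] for i in range(0, len(seq_b), 3)]
    if cod_a[-1] in STOP_CODONS and cod_b[-1] in STOP_CODONS:
        cod_a, cod_b = cod_a[:-1], cod_b[:-1]
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(cod_a, cod_b):
        sa, na = oracle_sites(ca)
        sb, nb = oracle_sites(cb)
        S += 0.5 * (sa + sb)
        N += 0.5 * (na + nb)
        sd, nd = oracle_pathway_diffs(ca, cb)
        Sd += sd
        Nd += nd
    ps, pn = Sd / S, Nd / N
    ds = -0.75 * math.log(1 - 4 * ps / 3) if 0 < ps < 0.75 else ps
    dn = -0.75 * math.log(1 - 4 * pn / 3) if 0 < pn < 0.75 else pn
    return dn, ds


def pad(core_a: str, core_b: str) -> tuple[str, str]:
    """Embed two short codon strings in an identical neutral context."""
    ctx = "ATG" + "GGT" * 8
    return ctx + core_a + "TAA", ctx + core_b + "TAA"


CODON_PAIRS = [
    ("TTT", "TTC"),  # single synonymous change
    ("TTT", "TTA"),  # single non-synonymous change
    ("AAA", "AGG"),  # two changes, mixed pathways
    ("ATG", "ATA"),  # Met -> Ile
    ("TGT", "TGC"),  # Cys synonymous
    ("GGG", "CCC"),  # three changes
    ("TCA", "TTA"),  # pathway passes near TAA/TGA stops
    ("CGA", "AGA"),  # Arg synonymous via first position
    ("ATT", "GCC"),  # three changes, all non-synonymous routes
    ("CTG", "TTA"),  # Leu -> Leu via two changes (synonymous overall)
]


@pytest.mark.parametrize("ca,cb", CODON_PAIRS, ids=[f"{a}-{b}" for a, b in CODON_PAIRS])
def test_ng86_matches_pathway_enumeration_oracle(ca, cb):
    a, b = pad(ca, cb)
    res = selection.pairwise_dnds(a, b)
    dn_o, ds_o = oracle_dnds(a, b)
    assert res.dn == pytest.approx(dn_o, abs=1e-12)
    assert res.ds == pytest.approx(ds_o, abs=1e-12)


def test_ng86_random_sequences_match_oracle(rng):
    for _ in range(5):
        a = random_cds(rng, 30)
        b = mutate_transferred_gene(a, 12, 0.5, int(rng.integers(1 << 30)))
        res = selection.pairwise_dnds(a, b)
        dn_o, ds_o = oracle_dnds(a, b)
        assert res.dn == pytest.approx(dn_o)
        assert res.ds == pytest.approx(ds_o)


# --------------------------------------------------------------------------
# pairwise_dnds behavior
# --------------------------------------------------------------------------

def test_dnds_identical_sequences(rng):
    g = random_cds(rng, 20)
    res = selection.pairwise_dnds(g, g)
    assert res.dn == 0.0 and res.ds == 0.0 and res.omega is None
    assert not res.saturated


def test_dnds_single_synonymous_difference():
    a, b = pad("TTT", "TTC")
    res = selection.pairwise_dnds(a, b)
    assert res.ds > 0 and res.dn == 0.0
    assert res.omega == 0.0


def test_dnds_single_nonsynonymous_difference():
    a, b = pad("TTT", "TTA")  # Phe -> Leu
    res = selection.pairwise_dnds(a, b)
    assert res.dn > 0 and res.ds == 0.0 and res.omega is None  # dS == 0: undefined


def test_dnds_symmetry(rng):
    a = random_cds(rng, 40)
    b = mutate_transferred_gene(a, 10, 0.3, 5)
    r1, r2 = selection.pairwise_dnds(a, b), selection.pairwise_dnds(b, a)
    assert r1.dn == pytest.approx(r2.dn) and r1.ds == pytest.approx(r2.ds)


def test_dnds_saturation_flag():
    # every Lys codon swapped to a maximally distant codon: pn >= 0.75
    a = "ATG" + "AAA" * 10 + "TAA"
    b = "ATG" + "CGC" * 10 + "TAA"
    res = selection.pairwise_dnds(a, b)
    assert res.saturated and res.omega is None


def test_dnds_input_validation(rng):
    with pytest.raises(ValueError):
        selection.pairwise_dnds("ACGT", "ACGT")
    with pytest.raises(ValueError):
        selection.pairwise_dnds("ATGTAATAA", "ATGGGGTAA")  # internal stop
    with pytest.raises(ValueError):
        selection.pairwise_dnds(random_cds(rng, 10), random_cds(rng, 11))


# --------------------------------------------------------------------------
# Lineage rates
# --------------------------------------------------------------------------

def test_lineage_rates_polarization():
    anc = "ATG" + "GGT" * 6 + "TAA"
    # recipient gains a non-synonymous change, donor a synonymous one
    rec = anc[:3] + "CGT" + anc[6:]          # GGT(Gly) -> CGT(Arg) at codon 1
    don = anc[:6] + "GGA" + anc[9:]          # GGT -> GGA (Gly) at codon 2
    rates = selection.lineage_rates(rec, don, anc)
    assert rates.recipient_subs == 1 and rates.donor_subs == 1
    assert rates.ambiguous_sites == 0
    assert rates.recipient.dn > 0 and rates.recipient.ds == 0
    assert rates.donor.ds > 0 and rates.donor.dn == 0


def test_lineage_rates_ambiguous_site_excluded():
    anc = "ATG" + "GGT" * 6 + "TAA"
    rec = anc[:4] + "A" + anc[5:]   # pos 4: G->A
    don = anc[:4] + "C" + anc[5:]   # pos 4: G->C
    out = anc[:4] + "T" + anc[5:]   # pos 4: G->T -> all three differ
    rates = selection.lineage_rates(rec, don, out)
    assert rates.ambiguous_sites == 1
    assert rates.recipient_subs == 0 and rates.donor_subs == 0


# --------------------------------------------------------------------------
# CAI
# --------------------------------------------------------------------------

def test_cai_of_reference_like_gene_is_one():
    gene = "ATG" + "AAA" * 20 + "TAA"
    usage = codon_usage_profile([gene])
    # every degenerate codon the gene uses is the most frequent in its group
    assert selection.cai(gene, usage) == pytest.approx(1.0)


def test_cai_hand_example():
    # reference uses AAA:AAG at 3:1 -> w(AAA)=1, w(AAG)=1/3
    ref = "ATG" + "AAA" * 3 + "AAG" + "TAA"
    usage = codon_usage_profile([ref])
    gene = "ATG" + "AAG" * 5 + "TAA"
    assert selection.cai(gene, usage) == pytest.approx(1.0 / 3.0)
    mixed = "ATG" + "AAA" + "AAG" + "TAA"  # geometric mean of 1 and 1/3
    assert selection.cai(mixed, usage) == pytest.approx(math.sqrt(1.0 / 3.0))


def test_cai_ignores_nondegenerate_codons():
    ref = "ATG" + "AAA" * 3 + "AAG" + "TAA"
    usage = codon_usage_profile([ref])
    with_met = "ATG" + "ATG" + "AAG" + "TAA"  # extra Met codon has no effect
    assert selection.cai(with_met, usage) == pytest.approx(1.0 / 3.0)


def test_cai_requires_degenerate_codons():
    ref = codon_usage_profile(["ATG" + "AAA" * 3 + "TAA"])
    with pytest.raises(ValueError):
        selection.cai("ATGTGG", ref)  # Met + Trp only


def test_relative_adaptiveness_shape():
    usage = codon_usage_profile(["ATG" + "AAA" * 5 + "TAA"])
    w = selection.relative_adaptiveness(usage)
    assert set(w) == set(selection.DEGENERATE_CODONS)
    assert all(0 < v <= 1 for v in w.values())
    with pytest.raises(ValueError):
        selection.relative_adaptiveness(np.ones(10))


# --------------------------------------------------------------------------
# Autolog summary
# --------------------------------------------------------------------------

def test_autolog_summary_counts_and_wilcoxon(rng):
    pairs = []
    for i in range(30):
        g = random_cds(rng, 100)
        pairs.append((mutate_transferred_gene(g, 12, 0.1, i), g))
    for _ in range(5):
        g = random_cds(rng, 100)
        pairs.append((g, g))  # zero-substitution autologs
    summary = selection.autolog_selection_summary(pairs)
    assert summary.n_total == 35
    assert summary.n_zero_substitution == 5
    assert summary.n_tested == 30
    assert summary.median_omega is not None and summary.median_omega < 1.0
    assert summary.p_ds_gt_dn is not None and summary.p_ds_gt_dn < 0.05


def test_autolog_summary_empty():
    summary = selection.autolog_selection_summary([])
    assert summary.n_total == 0 and summary.median_omega is None
    assert summary.p_ds_gt_dn is None


def test_autolog_summary_cai_comparison(rng):
    pairs = [((g := random_cds(rng, 60)), g)]
    cai_pairs = [(0.5, 0.9), (0.4, 0.8), (0.6, 0.95), (0.5, 0.7), (0.3, 0.9), (0.45, 0.85)]
    summary = selection.autolog_selection_summary(pairs, cai_pairs=cai_pairs)
    assert summary.p_cai_prophage_lt_genomic is not None
    assert summary.p_cai_prophage_lt_genomic < 0.05
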