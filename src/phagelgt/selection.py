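"""Substitution-pattern analysis of transferred genes.

Pairwise dN/dS by Nei–Gojobori (1986) counting with pathway averaging and
Jukes–Cantor correction; lineage-assigned substitution rates by outgroup
parsimony; codon adaptation index (CAI); and the paired autolog summary
(synonymous vs non-synonymous substitution load, prophage vs genomic copy CAI).

The counting estimator supports the downstream claims, which rest on relative
dN/dS magnitudes and paired comparisons rather than absolute ML estimates.
Externally computed ML values can be merged into reports via plain TSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genetic_code import (
    CODONS,
    CODON_INDEX,
    CODON_TO_AA,
    DEGENERATE_CODONS,
    DEGENERATE_INDEX,
    STOP_CODONS,
    SYNONYMOUS_GROUPS,
    NONSYN_SITES,
    PAIR_NONSYN,
    PAIR_SYN,
    SYN_SITES,
    codon_indices,
)

CAI_EPSILON = 0.01  # floor for relative adaptiveness of unseen codons


@dataclass(frozen=True)
class DnDsResult:
    dn: float
    ds: float
    omega: float | None  # None when dS == 0 (undefined ratio)
    saturated: bool      # Jukes–Cantor correction undefined (p >= 3/4)
    pn: float = 0.0      # raw proportion of non-synonymous differences
    ps: float = 0.0      # raw proportion of synonymous differences

    @property
    def defined(self) -> bool:
        return self.omega is not None and not self.saturated


def _check_codon_seq(seq: str, name: str) -> np.ndarray:
    if len(seq) % 3:
        raise ValueError(f"{name}: length not divisible by 3")
    idx = codon_indices(seq)
    stops = [i for i, ci in enumerate(idx[:-1]) if CODONS[ci] in STOP_CODONS]
    if stops:
        raise ValueError(f"{name}: internal stop codon at codon {stops[0]}")
    return idx


def _jc_correct(p: float) -> tuple[float, bool]:
    """Jukes–Cantor multiple-hit correction of a proportion of differences."""
    if p >= 0.75:
        return float("nan"), True
    if p == 0.0:
        return 0.0, False
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0), False


def pairwise_dnds(codon_seq_a: str, codon_seq_b: str) -> DnDsResult:
    """Nei–Gojobori dN, dS and omega between two aligned codon sequences.

    Synonymous/non-synonymous site counts are averaged over the two sequences;
    observed differences per codon are averaged over all shortest mutational
    pathways; Jukes–Cantor correction is applied to both proportions.
    """
    ia = _check_codon_seq(codon_seq_a, "sequence a")
    ib = _check_codon_seq(codon_seq_b, "sequence b")
    if ia.size != ib.size:
        raise ValueError("sequences differ in length")
    # exclude terminal stop codons (if present on both) from counting
    if CODONS[ia[-1]] in STOP_CODONS and CODONS[ib[-1]] in STOP_CODONS:
        ia, ib = ia[:-1], ib[:-1]
    syn_sites = 0.5 * (SYN_SITES[ia].sum() + SYN_SITES[ib].sum())
    non_sites = 0.5 * (NONSYN_SITES[ia].sum() + NONSYN_SITES[ib].sum())
    syn_diff = PAIR_SYN[ia, ib].sum()
    non_diff = PAIR_NONSYN[ia, ib].sum()
    ps = syn_diff / syn_sites if syn_sites > 0 else 0.0
    pn = non_diff / non_sites if non_sites > 0 else 0.0
    ds, sat_s = _jc_correct(ps)
    dn, sat_n = _jc_correct(pn)
    saturated = sat_s or sat_n
    if saturated:
        return DnDsResult(dn=dn, ds=ds, omega=None, saturated=True, pn=pn, ps=ps)
    omega = dn / ds if ds > 0 else None
    return DnDsResult(dn=dn, ds=ds, omega=omega, saturated=False, pn=pn, ps=ps)


# --------------------------------------------------------------------------
# Lineage-assigned rates (outgroup parsimony)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LineageRates:
    recipient: DnDsResult
    donor: DnDsResult
    recipient_subs: int
    donor_subs: int
    ambiguous_sites: int  # nucleotide sites where all three sequences differ


def lineage_rates(
    recipient_copy: str, donor_copy: str, outgroup_copy: str
) -> LineageRates:
    """Polarize substitutions between a recipient and donor copy with an
    outgroup, and estimate per-lineage dN/dS.

    A site where exactly one ingroup sequence differs from the other two is
    assigned to that ingroup's lineage (the shared state is taken as
    ancestral). Sites where all three sequences differ are unpolarizable and
    excluded (tallied). Per-lineage dN/dS is computed by NG86 counting between
    the inferred ancestral sequence and the lineage's observed sequence.
    """
    r = _check_codon_seq(recipient_copy, "recipient")
    d = _check_codon_seq(donor_copy, "donor")
    o = _check_codon_seq(outgroup_copy, "outgroup")
    if not (r.size == d.size == o.size):
        raise ValueError("sequences differ in length")

    rec = list(recipient_copy.upper())
    don = list(donor_copy.upper())
    out = list(outgroup_copy.upper())
    ancestral = list(rec)
    rec_derived = list(rec)
    don_derived = list(don)
    rec_subs = don_subs = ambiguous = 0
    for i in range(len(rec)):
        a, b, c = rec[i], don[i], out[i]
        if a == b:
            ancestral[i] = a
            rec_derived[i] = a
            don_derived[i] = a
            continue
        if b == c:  # recipient-lineage substitution
            ancestral[i] = b
            don_derived[i] = b
            rec_subs += 1
        elif a == c:  # donor-lineage substitution
            ancestral[i] = a
            rec_derived[i] = a
            don_subs += 1
        else:  # unpolarizable: neutralize the site in both comparisons
            ancestral[i] = a
            rec_derived[i] = a
            don_derived[i] = a
            ambiguous += 1
    anc = "".join(ancestral)
    # guard: parsimony states can in principle assemble a stop codon; such
    # codons are restored to the recipient state codon-wise
    anc = _sanitize_stops(anc, recipient_copy.upper())
    rec_res = pairwise_dnds(anc, _sanitize_stops("".join(rec_derived), anc))
    don_res = pairwise_dnds(anc, _sanitize_stops("".join(don_derived), anc))
    return LineageRates(
        recipient=rec_res,
        donor=don_res,
        recipient_subs=rec_subs,
        donor_subs=don_subs,
        ambiguous_sites=ambiguous,
    )


def _sanitize_stops(seq: str, fallback: str) -> str:
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    fb = [fallback[i : i + 3] for i in range(0, len(fallback), 3)]
    for j in range(len(codons) - 1):
        if codons[j] in STOP_CODONS:
            codons[j] = fb[j]
    return "".join(codons)


# --------------------------------------------------------------------------
# Codon adaptation index
# --------------------------------------------------------------------------

def relative_adaptiveness(reference_usage: np.ndarray) -> dict[str, float]:
    """Per-codon relative adaptiveness w = f(codon) / max f(synonymous codon).

    ``reference_usage`` is a 59-vector of relative synonymous codon
    frequencies (see :func:`phagelgt.seqsim.codon_usage_profile`). Codons with
    zero reference frequency are floored at ``CAI_EPSILON``.
    """
    usage = np.asarray(reference_usage, dtype=float)
    if usage.shape != (len(DEGENERATE_CODONS),):
        raise ValueError("reference usage must cover the 59 degenerate codons")
    w: dict[str, float] = {}
    for _aa, group in SYNONYMOUS_GROUPS.items():
        idx = [DEGENERATE_INDEX[c] for c in group]
        mx = usage[idx].max()
        if mx <= 0:
            raise ValueError("amino acid with all-zero reference frequencies")
        for c, i in zip(group, idx):
            w[c] = max(usage[i] / mx, CAI_EPSILON)
    return w


def cai(gene: str, reference_usage: np.ndarray) -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness over the
    gene's codons, excluding Met, Trp and stop codons."""
    w = relative_adaptiveness(reference_usage)
    logs = []
    for ci in codon_indices(gene):
        codon = CODONS[ci]
        if codon in w:
            logs.append(math.log(w[codon]))
    if not logs:
        raise ValueError("gene contains no degenerate codons")
    return math.exp(sum(logs) / len(logs))


# --------------------------------------------------------------------------
# Autolog summary
# --------------------------------------------------------------------------

@dataclass
class AutologSummary:
    n_total: int
    n_zero_substitution: int
    n_tested: int
    median_omega: float | None
    p_ds_gt_dn: float | None        # paired Wilcoxon, one-sided dS > dN
    p_cai_prophage_lt_genomic: float | None  # paired Wilcoxon, one-sided
    median_dn: float | None
    median_ds: float | None


def autolog_selection_summary(
    pairs: list[tuple[str, str]],
    cai_pairs: list[tuple[float, float]] | None = None,
) -> AutologSummary:
    """Paired substitution statistics for autologs.

    ``pairs`` holds (prophage_copy, genomic_copy) codon sequences per autolog.
    Copies with no nucleotide substitutions are tallied separately and excluded
    from the paired tests. ``cai_pairs`` optionally holds (cai_prophage,
    cai_genomic) values for the paired CAI comparison.
    """
    n_total = len(pairs)
    dns, dss, omegas = [], [], []
    n_zero = 0
    for prophage_copy, genomic_copy in pairs:
        if prophage_copy.upper() == genomic_copy.upper():
            n_zero += 1
            continue
        res = pairwise_dnds(prophage_copy, genomic_copy)
        if res.saturated:
            continue
        dns.append(res.dn)
        dss.append(res.ds)
        if res.omega is not None:
            omegas.append(res.omega)
    n_tested = len(dns)
    p_ds = None
    if n_tested >= 1 and any(abs(a - b) > 0 for a, b in zip(dss, dns)):
        p_ds = float(
            stats.wilcoxon(dss, dns, alternative="greater", zero_method="zsplit").pvalue
        )
    p_cai = None
    if cai_pairs:
        pro = [a for a, _ in cai_pairs]
        gen = [b for _, b in cai_pairs]
        if any(abs(a - b) > 0 for a, b in zip(pro, gen)):
            p_cai = float(
                stats.wilcoxon(gen, pro, alternative="greater", zero_method="zsplit").pvalue
            )
    return AutologSummary(
        n_total=n_total,
        n_zero_substitution=n_zero,
        n_tested=n_tested,
        median_omega=float(np.median(omegas)) if omegas else None,
        p_ds_gt_dn=p_ds,
        p_cai_prophage_lt_genomic=p_cai,
        median_dn=float(np.median(dns)) if dns else None,
        median_ds=float(np.median(dss)) if dss else None,
    )
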