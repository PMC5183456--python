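"""Donor inference for bacterial genes encoded in prophages.

For each prophage-encoded bacterial gene (the recipient copy), homologs are
collected from all genome proteins at a global-identity threshold (>= 90% to
the query). Two-member families resolve directly (the unique homolog's genome
is the donor). Larger families get a neighbor-joining tree on Poisson-corrected
protein distances, midpoint-rooted; the donor is the genome of the recipient
unit's sister group when that group maps to exactly one genome. Trees where
the sister group spans several genomes (donor clade) or the recipient unit
spans several recipient genomes (recipient clade) are excluded, mirroring the
conservative single-taxon sister rule. Paraphyletic recipients trigger the
consolidation test; rejected consolidations are excluded.

Multiple prophage-gene copies from the same recipient genome count as one
recipient taxon for the monophyly and sister logic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import seqsim, trees
from .datatypes import Dataset, Gene

HOMOLOG_IDENTITY_THRESHOLD = 90.0

EXCLUSION_REASONS = (
    "none", "no_homolog", "donor_clade", "recipient_clade", "consolidation_rejected",
)


@dataclass
class DonorCall:
    gene_id: str
    recipient: str
    donor: str | None
    exclusion_reason: str = "none"
    p_consolidation: float | None = None
    family_size: int = 1
    poisson_ok: bool = True
    donor_gene_id: str | None = None  # highest-identity homolog in the donor genome

    def __post_init__(self):
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.exclusion_reason!r}")
        if (self.donor is not None) != (self.exclusion_reason == "none"):
            raise ValueError("donor must be present iff not excluded")

    @property
    def excluded(self) -> bool:
        return self.exclusion_reason != "none"


@dataclass
class HomologFamily:
    query_id: str
    members: dict[str, Gene]  # gene id -> Gene, query included
    identities: dict[str, float]  # member gene id -> identity to query

    @property
    def size(self) -> int:
        return len(self.members)


def build_homolog_family(
    query: Gene,
    candidates: dict[str, Gene],
    similarity_threshold: float = HOMOLOG_IDENTITY_THRESHOLD,
) -> HomologFamily:
    """Query + every candidate protein with global identity >= threshold.

    The threshold is inclusive (a candidate at exactly the threshold is kept).
    Candidates are screened with an edit-distance bound and re-scored exactly
    near the threshold.
    """
    if not query.protein:
        raise ValueError("empty query protein")
    members = {query.gene_id: query}
    identities = {query.gene_id: 100.0}
    floor = similarity_threshold - 5.0
    for gid, gene in candidates.items():
        if gid == query.gene_id:
            continue
        mn = min(len(query.protein), len(gene.protein))
        k = seqsim.max_edits_for_identity(floor, mn)
        if seqsim.identity_upper_bound(query.protein, gene.protein, max_edits=k) < floor:
            continue
        ident = seqsim.global_align_identity(query.protein, gene.protein)
        if ident >= similarity_threshold:
            members[gid] = gene
            identities[gid] = ident
    return HomologFamily(query_id=query.gene_id, members=members, identities=identities)


def build_gene_tree(family: HomologFamily):
    """Midpoint-rooted NJ tree over the family (size >= 3 required).

    Returns (tree, labels, dist, poisson_ok). Family members must be
    positionally aligned (equal-length proteins); supply pre-aligned sequences
    for indel-containing real data.
    """
    if family.size < 3:
        raise ValueError("families of size < 3 bypass tree building")
    labels = sorted(family.members)
    seqs = [family.members[g].protein for g in labels]
    dist, poisson_ok = trees.protein_distance_matrix(seqs)
    tree = trees.nj_tree(dist, labels)
    tree = trees.midpoint_root(tree)
    return tree, labels, dist, poisson_ok


def _recipient_flags(family: HomologFamily, is_recipient: Callable[[Gene], bool]) -> set[str]:
    return {gid for gid, g in family.members.items() if is_recipient(g)}


def call_donor(
    family: HomologFamily,
    is_recipient: Callable[[Gene], bool],
    alpha: float = 0.05,
    n_boot: int = 10000,
    seed: int = 0,
) -> DonorCall:
    """Resolve the most likely donor genome for the family's query gene."""
    query = family.members[family.query_id]
    recipient_genome = query.genome_id
    if family.size < 2:
        return DonorCall(query.gene_id, recipient_genome, None, "no_homolog",
                         family_size=family.size)
    if family.size == 2:
        other = next(g for gid, g in family.members.items() if gid != family.query_id)
        return DonorCall(query.gene_id, recipient_genome, other.genome_id,
                         family_size=2, donor_gene_id=other.gene_id)

    tree, labels, dist, poisson_ok = build_gene_tree(family)
    recipient_leaves = _recipient_flags(family, is_recipient)
    if family.query_id not in recipient_leaves:
        recipient_leaves.add(family.query_id)

    p_cons = None
    if not trees.test_recipient_monophyly(tree, recipient_leaves):
        seqs = {gid: family.members[gid].protein for gid in labels}
        res = trees.consolidation_test(
            seqs, tree, recipient_leaves, dist, labels,
            alpha=alpha, n_boot=n_boot, seed=seed,
        )
        p_cons = res.p_value
        if not res.accepted or res.constrained_tree is None:
            return DonorCall(query.gene_id, recipient_genome, None,
                             "consolidation_rejected", p_consolidation=p_cons,
                             family_size=family.size, poisson_ok=poisson_ok)
        tree = res.constrained_tree

    # recipient unit: all recipient-flagged leaves; same-genome copies count
    # as a single recipient taxon
    recipient_genomes = {family.members[g].genome_id for g in recipient_leaves}
    if len(recipient_genomes) > 1:
        return DonorCall(query.gene_id, recipient_genome, None, "recipient_clade",
                         p_consolidation=p_cons, family_size=family.size,
                         poisson_ok=poisson_ok)

    sisters = trees.sister_leaves(tree, recipient_leaves)
    sister_genomes = sorted({family.members[g].genome_id for g in sisters})
    if len(sister_genomes) != 1:
        return DonorCall(query.gene_id, recipient_genome, None, "donor_clade",
                         p_consolidation=p_cons, family_size=family.size,
                         poisson_ok=poisson_ok)
    # donor gene: the sister leaf closest to the query (ties: lexicographic id)
    donor_gene = min(sorted(sisters), key=lambda g: -family.identities.get(g, 0.0))
    return DonorCall(query.gene_id, recipient_genome, sister_genomes[0],
                     p_consolidation=p_cons, family_size=family.size,
                     poisson_ok=poisson_ok, donor_gene_id=donor_gene)


# --------------------------------------------------------------------------
# Stage driver
# --------------------------------------------------------------------------

def infer_donors(
    dataset: Dataset,
    similarity_threshold: float = HOMOLOG_IDENTITY_THRESHOLD,
    alpha: float = 0.05,
    n_boot: int = 10000,
    seed: int = 0,
) -> list[DonorCall]:
    """Donor calls for every bacterial-flagged prophage gene in the dataset."""
    all_genes = dataset.all_genes()
    queries = dataset.prophage_bacterial_genes()
    # candidate pool: every annotated protein except prophage viral genes
    candidates = {
        gid: g for gid, g in all_genes.items() if g.gene_class != "viral"
    }

    def is_recipient(gene: Gene) -> bool:
        return gene.in_prophage and gene.gene_class == "bacterial"

    calls = []
    for query in sorted(queries, key=lambda g: g.gene_id):
        family = build_homolog_family(query, candidates, similarity_threshold)
        calls.append(call_donor(family, is_recipient, alpha=alpha,
                                n_boot=n_boot, seed=seed))
    return calls
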