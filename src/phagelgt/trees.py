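"""Gene-tree construction and topology testing for donor inference.

Neighbor-joining on Poisson-corrected protein distances (the synthetic data is
indel-free, so family members are positionally aligned; pre-aligned families
are accepted for real inputs), midpoint rooting (dendropy), recipient-monophyly
checks, and the consolidation test: a RELL bootstrap comparison of the
unconstrained tree against a tree with all recipient leaves forced into one
clade, under a 20-state Poisson (equal-rates) protein model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}
N_STATES = 20


# --------------------------------------------------------------------------
# Distances
# --------------------------------------------------------------------------

def protein_distance_matrix(seqs: list[str]) -> tuple[np.ndarray, bool]:
    """Pairwise Poisson-corrected distances d = -ln(1 - p) for aligned protein
    sequences. Returns (matrix, poisson_ok): when any pair saturates the
    correction (p = 1) the whole matrix falls back to p-distances and
    ``poisson_ok`` is False.
    """
    lens = {len(s) for s in seqs}
    if len(lens) != 1:
        raise ValueError("family sequences are not aligned (unequal lengths)")
    arr = np.array([np.frombuffer(s.upper().encode(), dtype=np.uint8) for s in seqs])
    n = len(seqs)
    p = np.zeros((n, n))
    for i in range(n):
        p[i] = (arr != arr[i]).mean(axis=1)
    if np.any(p >= 1.0):
        return p, False
    with np.errstate(divide="ignore"):
        d = -np.log(1.0 - p)
    np.fill_diagonal(d, 0.0)
    return d, True


# --------------------------------------------------------------------------
# Neighbor joining
# --------------------------------------------------------------------------

def _nj_merge_order(
    dist: np.ndarray, labels: list[str], first_group: set[int] | None = None
) -> str:
    """NJ with optional constraint: indices in ``first_group`` are joined among
    themselves first (building a clade), then joining proceeds normally.
    Returns a Newick string (rooted arbitrarily at the final join).
    Deterministic: ties resolved by smallest (i, j) in row-major order.
    """
    n = dist.shape[0]
    if n == 1:
        return f"{labels[0]}:0;"
    if n == 2:
        d = max(dist[0, 1], 0.0)
        return f"({labels[0]}:{d / 2:.10g},{labels[1]}:{d / 2:.10g});"

    D = dist.astype(float).copy()
    newicks = list(labels)
    active = list(range(n))
    in_group = set(first_group or set())

    def q_matrix(Didx: np.ndarray, m: int) -> np.ndarray:
        r = Didx.sum(axis=1)
        q = (m - 2) * Didx - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        return q

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        q = q_matrix(sub, m)
        group_pos = [t for t, g in enumerate(active) if g in in_group]
        if len(group_pos) > 1:
            # restrict the choice to pairs inside the constrained group
            mask = np.full_like(q, np.inf)
            gp = np.array(group_pos)
            mask[np.ix_(gp, gp)] = q[np.ix_(gp, gp)]
            np.fill_diagonal(mask, np.inf)
            q = mask
        fi, fj = np.unravel_index(int(np.argmin(q)), q.shape)
        if fi > fj:
            fi, fj = fj, fi
        i, j = active[fi], active[fj]
        r = sub.sum(axis=1)
        dij = sub[fi, fj]
        li = 0.5 * dij + (r[fi] - r[fj]) / (2.0 * (m - 2)) if m > 2 else 0.5 * dij
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        # new node replaces i; distances by the reduction formula
        new_newick = f"({newicks[i]}:{li:.10g},{newicks[j]}:{lj:.10g})"
        for g in active:
            if g in (i, j):
                continue
            D[i, g] = D[g, i] = 0.5 * (D[i, g] + D[j, g] - dij)
        newicks[i] = new_newick
        active.remove(j)
        if j in in_group:
            in_group.discard(j)
            # the merged node inherits group membership only if both were inside
            if i not in in_group:
                in_group.discard(i)
        elif i in in_group:
            in_group.discard(i)

    i, j = active
    d = max(D[i, j], 0.0)
    return f"({newicks[i]}:{d / 2:.10g},{newicks[j]}:{d / 2:.10g});"


def nj_tree(dist: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix."""
    newick = _nj_merge_order(dist, labels)
    return parse_newick(newick)


def constrained_nj_tree(
    dist: np.ndarray, labels: list[str], constrained_labels: set[str]
) -> dendropy.Tree:
    """NJ forced to join the constrained labels into one clade first."""
    group = {i for i, lab in enumerate(labels) if lab in constrained_labels}
    newick = _nj_merge_order(dist, labels, first_group=group)
    return parse_newick(newick)


def parse_newick(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    # trees here are always handled as rooted; leaving them unrooted lets
    # dendropy collapse the root bifurcation during MRCA queries
    tree.is_rooted = True
    return tree


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


# --------------------------------------------------------------------------
# Rooting and clade logic
# --------------------------------------------------------------------------

def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root the tree at the midpoint of its longest leaf-to-leaf path.

    Negative/None branch lengths are clamped to 0 first. An all-zero tree is
    rooted at the first edge in postorder (deterministic, degenerate case).
    """
    for edge in tree.preorder_edge_iter():
        if edge.length is None or edge.length < 0:
            edge.length = 0.0
    total = sum(e.length or 0.0 for e in tree.preorder_edge_iter())
    if total == 0.0:
        leaves = tree.leaf_nodes()
        if len(leaves) > 1:
            tree.reroot_at_edge(leaves[0].edge, update_bipartitions=True)
        return tree
    tree.reroot_at_midpoint(update_bipartitions=True)
    return tree


def leaf_labels(node: dendropy.Node) -> set[str]:
    return {lf.taxon.label for lf in node.leaf_iter()}


def recipient_mrca(tree: dendropy.Tree, recipient_labels: set[str]) -> dendropy.Node:
    if len(recipient_labels) == 1:
        label = next(iter(recipient_labels))
        return next(
            lf for lf in tree.leaf_node_iter() if lf.taxon.label == label
        )
    taxa = [t for t in tree.taxon_namespace if t.label in recipient_labels]
    return tree.mrca(taxa=taxa)


def test_recipient_monophyly(tree: dendropy.Tree, recipient_labels: set[str]) -> bool:
    """True iff the recipient-flagged leaves form one clade in the rooted tree.
    A single recipient leaf is monophyletic by definition."""
    if not recipient_labels:
        raise ValueError("no recipient leaves")
    if len(recipient_labels) == 1:
        return True
    node = recipient_mrca(tree, recipient_labels)
    return leaf_labels(node) == recipient_labels


def sister_leaves(tree: dendropy.Tree, clade_labels: set[str]) -> set[str]:
    """Leaf labels of the sister group of the (monophyletic) clade."""
    node = recipient_mrca(tree, clade_labels)
    if len(clade_labels) > 1 and leaf_labels(node) != clade_labels:
        raise ValueError("clade is not monophyletic")
    parent = node.parent_node
    if parent is None:
        return set()
    return leaf_labels(parent) - leaf_labels(node)


# --------------------------------------------------------------------------
# Poisson-model likelihood and the RELL consolidation test
# --------------------------------------------------------------------------

def _transition_matrices(tree: dendropy.Tree) -> dict[int, np.ndarray]:
    mats = {}
    for node in tree.preorder_node_iter():
        t = node.edge.length or 0.0
        t = max(t, 0.0)
        e = math.exp(-N_STATES * t / (N_STATES - 1))
        p_same = 1.0 / N_STATES + (1.0 - 1.0 / N_STATES) * e
        p_diff = (1.0 - e) / N_STATES
        m = np.full((N_STATES, N_STATES), p_diff)
        np.fill_diagonal(m, p_same)
        mats[id(node)] = m
    return mats


def site_log_likelihoods(tree: dendropy.Tree, sequences: dict[str, str]) -> np.ndarray:
    """Per-site log-likelihood of aligned protein sequences on the tree under
    the 20-state Poisson model (uniform stationary frequencies)."""
    lens = {len(s) for s in sequences.values()}
    if len(lens) != 1:
        raise ValueError("sequences not aligned")
    L = lens.pop()
    mats = _transition_matrices(tree)

    def encode(seq: str) -> np.ndarray:
        part = np.zeros((L, N_STATES))
        for i, c in enumerate(seq.upper()):
            k = _AA_INDEX.get(c)
            if k is None:
                part[i, :] = 1.0  # ambiguous residue
            else:
                part[i, k] = 1.0
        return part

    def prune(node: dendropy.Node) -> np.ndarray:
        if node.is_leaf():
            partial = encode(sequences[node.taxon.label])
        else:
            partial = np.ones((L, N_STATES))
            for child in node.child_nodes():
                partial = partial * prune(child)
        m = mats[id(node)]
        return partial @ m.T

    root = tree.seed_node
    partial = np.ones((L, N_STATES))
    for child in root.child_nodes():
        partial = partial * prune(child)
    site_lik = partial.mean(axis=1)  # uniform 1/20 prior
    return np.log(np.maximum(site_lik, 1e-300))


@dataclass
class ConsolidationResult:
    accepted: bool
    p_value: float
    constrained_tree: dendropy.Tree | None
    delta_lnl: float  # constrained minus unconstrained total log-likelihood


def consolidation_test(
    sequences: dict[str, str],
    unconstrained: dendropy.Tree,
    recipient_labels: set[str],
    dist: np.ndarray,
    labels: list[str],
    alpha: float = 0.05,
    n_boot: int = 10000,
    seed: int = 0,
) -> ConsolidationResult:
    """Test whether forcing the recipients into one clade is significantly
    worse than the unconstrained tree.

    Builds a constrained NJ tree (recipients joined first), computes per-site
    log-likelihoods of both topologies under the Poisson protein model, and
    bootstraps the summed log-likelihood difference over sites (RELL). The
    p-value is the fraction of bootstrap replicates in which the constrained
    topology is at least as likely; accepted iff p >= alpha.
    """
    try:
        constrained = constrained_nj_tree(dist, labels, recipient_labels)
        constrained = midpoint_root(constrained)
    except Exception:
        return ConsolidationResult(False, 0.0, None, float("-inf"))
    lnl_u = site_log_likelihoods(unconstrained, sequences)
    lnl_c = site_log_likelihoods(constrained, sequences)
    delta = lnl_c - lnl_u
    if np.allclose(delta, 0.0):
        return ConsolidationResult(True, 1.0, constrained, 0.0)
    rng = np.random.default_rng(seed)
    L = delta.size
    idx = rng.integers(0, L, size=(n_boot, L))
    sums = delta[idx].sum(axis=1)
    p = float(np.mean(sums >= 0.0))
    return ConsolidationResult(
        accepted=p >= alpha, p_value=p, constrained_tree=constrained,
        delta_lnl=float(delta.sum()),
    )
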