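"""Protein-family construction and orthologous-prophage clustering.

Prophage proteins are linked by reciprocal best hits under exact global
alignment (pairs below the identity cutoff are excluded), clustered into
orthologous protein families by Markov clustering (MCL), and prophages sharing
more than a threshold fraction of protein families (Jaccard index, strict
inequality) are merged into one phage entity by single linkage. Unclustered
prophages become singleton phage entities.

All-vs-all alignment is exact: a cheap edit-distance bound (edlib) only skips
pairs that provably cannot reach the decision threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from . import seqsim

PREFILTER_MARGIN = 5.0  # percentage points of slack on the identity bound


@dataclass
class ProteinFamily:
    family_id: str
    gene_ids: list[str]
    genome_ids: list[str]


@dataclass
class PhageEntity:
    phage_id: str
    member_prophages: list[str]

    @property
    def is_singleton(self) -> bool:
        return len(self.member_prophages) == 1


# --------------------------------------------------------------------------
# Reciprocal best hits
# --------------------------------------------------------------------------

def pairwise_identities(
    proteins: dict[str, tuple[str, str]],
    min_identity: float,
) -> dict[tuple[str, str], float]:
    """Exact global percent identity for every protein pair that can reach
    ``min_identity - PREFILTER_MARGIN``; other pairs are omitted.

    ``proteins`` maps gene id -> (genome id, protein sequence).
    """
    ids = sorted(proteins)
    floor = max(min_identity - PREFILTER_MARGIN, 1.0)
    out: dict[tuple[str, str], float] = {}
    for i, x in enumerate(ids):
        gx, sx = proteins[x]
        for y in ids[i + 1:]:
            gy, sy = proteins[y]
            if gx == gy:
                continue
            mn = min(len(sx), len(sy))
            k = seqsim.max_edits_for_identity(floor, mn)
            if seqsim.identity_upper_bound(sx, sy, max_edits=k) < floor:
                continue
            ident = seqsim.global_align_identity(sx, sy)
            out[(x, y)] = ident
    return out


def all_against_all_rbh(
    proteins: dict[str, tuple[str, str]],
    identity_threshold: float = 95.0,
) -> dict[tuple[str, str], float]:
    """Reciprocal best hit pairs across genomes with identity >= threshold.

    For each protein, its best match within every other genome is the highest
    exact global identity (ties broken by lexicographic gene id). A pair is
    kept iff each member is the other's best match in the partner genome and
    the identity is at least the threshold (strictly below is excluded).
    Returns {(gene_a, gene_b) sorted: identity}.
    """
    if len(proteins) < 2:
        return {}
    idents = pairwise_identities(proteins, identity_threshold)
    # best match of gene x within genome g
    best: dict[tuple[str, str], tuple[float, str]] = {}
    for (x, y), ident in idents.items():
        gx, gy = proteins[x][0], proteins[y][0]
        for query, target, tgenome in ((x, y, gy), (y, x, gx)):
            key = (query, tgenome)
            cur = best.get(key)
            if cur is None or ident > cur[0] or (ident == cur[0] and target < cur[1]):
                best[key] = (ident, target)
    out: dict[tuple[str, str], float] = {}
    for (x, y), ident in idents.items():
        if ident < identity_threshold:
            continue
        gx, gy = proteins[x][0], proteins[y][0]
        if best[(x, gy)][1] == y and best[(y, gx)][1] == x:
            out[(x, y)] = ident
    return out


# --------------------------------------------------------------------------
# Markov clustering
# --------------------------------------------------------------------------

def markov_cluster(
    nodes: list[str],
    edges: dict[tuple[str, str], float],
    inflation: float = 2.0,
    expansion: int = 2,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[list[list[str]], bool]:
    """Markov clustering of a weighted undirected graph.

    Column-stochastic normalization, then alternating expansion (matrix power)
    and inflation (elementwise power + renormalization) until the matrix is
    stable. Returns (clusters, converged); clusters partition the node set and
    are sorted deterministically. Non-convergence at ``max_iter`` returns the
    partition of the current matrix with ``converged=False``.
    """
    nodes = sorted(nodes)
    n = len(nodes)
    if n == 0:
        return [], True
    index = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for (a, b), w in edges.items():
        if w < 0:
            raise ValueError("negative edge weight")
        i, j = index[a], index[b]
        m[i, j] = m[j, i] = max(m[i, j], w)
    # self-loop per node = its maximum incident edge weight (>= 1). With a
    # fixed unit loop, a heavily weighted two-node edge oscillates under
    # expansion and the pair is wrongly split into singletons.
    loops = np.maximum(m.max(axis=1), 1.0)
    np.fill_diagonal(m, np.maximum(m.diagonal(), loops))

    def normalize(x: np.ndarray) -> np.ndarray:
        s = x.sum(axis=0, keepdims=True)
        s[s == 0] = 1.0
        return x / s

    m = normalize(m)
    converged = False
    for _ in range(max_iter):
        expanded = np.linalg.matrix_power(m, expansion)
        inflated = normalize(expanded ** inflation)
        inflated[inflated < 1e-12] = 0.0
        inflated = normalize(inflated)
        if np.abs(inflated - m).max() < tol:
            m = inflated
            converged = True
            break
        m = inflated

    # attractors: rows with nonzero diagonal; cluster = their supported columns
    eps = 1e-9
    assigned = -np.ones(n, dtype=int)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i in range(n):
        if m[i, i] > eps:
            members = np.nonzero(m[i] > eps)[0]
            for j in members:
                union(i, int(j))
                assigned[j] = 1
    # nodes not covered by any attractor row become singletons
    clusters_map: dict[int, list[str]] = {}
    for j in range(n):
        root = find(j) if assigned[j] > 0 else j
        clusters_map.setdefault(root if assigned[j] > 0 else -j - 1, []).append(nodes[j])
    clusters = sorted((sorted(c) for c in clusters_map.values()), key=lambda c: c[0])
    return clusters, converged


def build_protein_families(
    proteins: dict[str, tuple[str, str]],
    identity_threshold: float = 95.0,
    inflation: float = 2.0,
) -> list[ProteinFamily]:
    """RBH graph + MCL -> orthologous protein families (singletons included)."""
    rbh = all_against_all_rbh(proteins, identity_threshold)
    clusters, _ = markov_cluster(sorted(proteins), rbh, inflation=inflation)
    families = []
    for i, cluster in enumerate(clusters):
        families.append(ProteinFamily(
            family_id=f"PF{i:05d}",
            gene_ids=cluster,
            genome_ids=sorted({proteins[g][0] for g in cluster}),
        ))
    return families


# --------------------------------------------------------------------------
# Orthologous prophages
# --------------------------------------------------------------------------

def prophage_content_similarity(a: set[str], b: set[str]) -> float | None:
    """Jaccard index of two prophages' protein-family sets; None when both
    sets are empty (undefined)."""
    if not a and not b:
        return None
    return len(a & b) / len(a | b)


def hypergeometric_content_similarity(a: set[str], b: set[str], n_total: int) -> float:
    """Alternative content-similarity: -log10 hypergeometric tail probability
    of observing at least |a∩b| shared families out of ``n_total``."""
    k = len(a & b)
    if k == 0:
        return 0.0
    p = _stats.hypergeom.sf(k - 1, n_total, len(a), len(b))
    return float(-np.log10(max(p, 1e-300)))


def cluster_orthologous_prophages(
    prophage_families: dict[str, set[str]],
    has_bacterial_gene: dict[str, bool],
    threshold: float = 0.7,
    metric: str = "jaccard",
    n_total_families: int | None = None,
) -> list[PhageEntity]:
    """Single-linkage clustering of prophages over pairs whose gene-content
    similarity is strictly greater than ``threshold``.

    Prophages without any bacterial-flagged gene are excluded beforehand
    (phage-only prophages carry no transduction signal). Unclustered prophages
    become singleton phage entities. Deterministic: entities are ordered by
    their lexicographically smallest member.
    """
    ids = sorted(p for p in prophage_families if has_bacterial_gene.get(p, False))
    parent = {p: p for p in ids}

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if metric == "jaccard":
                sim = prophage_content_similarity(prophage_families[a], prophage_families[b])
            elif metric == "hypergeometric":
                if n_total_families is None:
                    raise ValueError("hypergeometric metric needs n_total_families")
                sim = hypergeometric_content_similarity(
                    prophage_families[a], prophage_families[b], n_total_families
                )
            else:
                raise ValueError(f"unknown metric {metric!r}")
            if sim is not None and sim > threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    groups: dict[str, list[str]] = {}
    for p in ids:
        groups.setdefault(find(p), []).append(p)
    entities = []
    for i, root in enumerate(sorted(groups)):
        entities.append(PhageEntity(phage_id=f"PH{i:05d}", member_prophages=sorted(groups[root])))
    return entities
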