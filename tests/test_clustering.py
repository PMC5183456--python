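import numpy as np
import pytest

from phagelgt import clustering

from conftest import random_protein


# --------------------------------------------------------------------------
# Reference MCL (independent implementation, same parameters)
# --------------------------------------------------------------------------

def reference_mcl(nodes, edges, inflation=2.0, expansion=2, max_iter=200, tol=1e-6):
    """Straightforward MCL written independently of the package code.

    Builds the column-stochastic matrix with unit self-loops, alternates
    expansion and inflation with pruning, and reads clusters off attractor
    rows, merging overlapping clusters.
    """
    nodes = sorted(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    mat = np.zeros((n, n))
    for (a, b), w in edges.items():
        mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = max(mat[idx[a], idx[b]], w)
    for i in range(n):
        mat[i, i] = max(mat[i, i], mat[i].max(), 1.0)  # loop = max incident weight
    mat = mat / mat.sum(axis=0)
    for _ in range(max_iter):
        new = np.linalg.matrix_power(mat, expansion) ** inflation
        new = new / new.sum(axis=0)
        new[new < 1e-12] = 0.0
        new = new / new.sum(axis=0)
        if np.max(np.abs(new - mat)) < tol:
            mat = new
            break
        mat = new
    raw = [set(np.nonzero(mat[i] > 1e-9)[0]) for i in range(n) if mat[i, i] > 1e-9]
    merged: list[set] = []
    for cl in raw:
        hits = [m for m in merged if m & cl]
        for m in hits:
            cl |= m
            merged.remove(m)
        merged.append(cl)
    covered = set().union(*merged) if merged else set()
    merged.extend({j} for j in range(n) if j not in covered)
    out = sorted((sorted(nodes[j] for j in cl) for cl in merged), key=lambda c: c[0])
    return out


TOY_GRAPHS = [
    # two triangles joined by one weak edge
    (list("abcdef"),
     {("a", "b"): 1, ("b", "c"): 1, ("a", "c"): 1,
      ("d", "e"): 1, ("e", "f"): 1, ("d", "f"): 1, ("c", "d"): 0.1}),
    # path of four nodes
    (list("abcd"), {("a", "b"): 1, ("b", "c"): 1, ("c", "d"): 1}),
    # star
    (list("abcde"), {("a", x): 1 for x in "bcde"}),
    # barbell: two 4-cliques bridged
    (list("abcdwxyz"),
     {(u, v): 1 for i, u in enumerate("abcd") for v in "abcd"[i + 1:]}
     | {(u, v): 1 for i, u in enumerate("wxyz") for v in "wxyz"[i + 1:]}
     | {("d", "w"): 1}),
    # two components plus an isolated node
    (list("abcde"), {("a", "b"): 2, ("c", "d"): 2}),
]


@pytest.mark.parametrize("nodes,edges", TOY_GRAPHS, ids=[f"toy{i}" for i in range(5)])
def test_mcl_matches_reference_on_toys(nodes, edges):
    ours, converged = clustering.markov_cluster(nodes, edges)
    assert converged
    assert ours == reference_mcl(nodes, edges)


def test_mcl_is_a_partition():
    nodes, edges = TOY_GRAPHS[3]
    clusters, _ = clustering.markov_cluster(nodes, edges)
    flat = [v for c in clusters for v in c]
    assert sorted(flat) == sorted(nodes)
    assert len(flat) == len(set(flat))


def test_mcl_empty_and_singleton():
    assert clustering.markov_cluster([], {}) == ([], True)
    assert clustering.markov_cluster(["x"], {})[0] == [["x"]]


def test_mcl_rejects_negative_weight():
    with pytest.raises(ValueError):
        clustering.markov_cluster(["a", "b"], {("a", "b"): -1.0})


def test_mcl_higher_inflation_never_coarser():
    nodes, edges = TOY_GRAPHS[0]
    fine, _ = clustering.markov_cluster(nodes, edges, inflation=4.0)
    coarse, _ = clustering.markov_cluster(nodes, edges, inflation=1.4)
    assert len(fine) >= len(coarse)


# --------------------------------------------------------------------------
# Reciprocal best hits
# --------------------------------------------------------------------------

def make_protein(base: str, n_mismatch: int) -> str:
    out = list(base)
    for i in range(n_mismatch):
        out[i] = "W" if out[i] != "W" else "Y"
    return "".join(out)


def test_rbh_simple_pair(rng):
    base = random_protein(rng, 100)
    proteins = {"g1|a": ("g1", base), "g2|b": ("g2", base)}
    rbh = clustering.all_against_all_rbh(proteins, identity_threshold=95.0)
    assert rbh == {("g1|a", "g2|b"): 100.0}


def test_rbh_boundary_949_excluded_950_included(rng):
    base = random_protein(rng, 1000)
    # 95.0% identity: 50 mismatches in 1000 -> included (>= threshold)
    at = {"g1|a": ("g1", base), "g2|b": ("g2", make_protein(base, 50))}
    assert ("g1|a", "g2|b") in clustering.all_against_all_rbh(at, 95.0)
    # 94.9% identity: 51 mismatches -> excluded (strictly below threshold)
    below = {"g1|a": ("g1", base), "g2|b": ("g2", make_protein(base, 51))}
    assert clustering.all_against_all_rbh(below, 95.0) == {}


def test_rbh_same_genome_never_paired(rng):
    base = random_protein(rng, 80)
    proteins = {"g1|a": ("g1", base), "g1|b": ("g1", base)}
    assert clustering.all_against_all_rbh(proteins) == {}


def test_rbh_requires_reciprocity(rng):
    base = random_protein(rng, 100)
    close = make_protein(base, 1)  # 99% to base, 100% to itself
    proteins = {
        "g1|a": ("g1", base),
        "g2|b": ("g2", close),
        "g1|c": ("g1", close),  # same genome as a; b's best in g1 is c, not a
    }
    rbh = clustering.all_against_all_rbh(proteins, 95.0)
    assert ("g1|a", "g2|b") not in rbh
    assert ("g1|c", "g2|b") in rbh


def test_prefilter_never_drops_qualifying_pairs(rng):
    # identities near the threshold from both sides; compare against a run
    # with the prefilter effectively disabled via direct exact alignment
    base = random_protein(rng, 60)
    proteins = {"g0|q": ("g0", base)}
    for i in range(8):
        proteins[f"g{i + 1}|t"] = (f"g{i + 1}", make_protein(base, i))
    got = clustering.pairwise_identities(proteins, min_identity=95.0)
    from phagelgt.seqsim import global_align_identity
    for (x, y), ident in got.items():
        assert ident == pytest.approx(global_align_identity(proteins[x][1], proteins[y][1]))
    exact_above = {
        (x, y)
        for i, x in enumerate(sorted(proteins))
        for y in sorted(proteins)[i + 1:]
        if proteins[x][0] != proteins[y][0]
        and global_align_identity(proteins[x][1], proteins[y][1]) >= 95.0
    }
    assert exact_above <= set(got)


def test_build_protein_families_partition(rng):
    base1, base2 = random_protein(rng, 90), random_protein(rng, 90)
    proteins = {
        "g1|a": ("g1", base1), "g2|a": ("g2", base1), "g3|a": ("g3", make_protein(base1, 1)),
        "g1|b": ("g1", base2), "g2|b": ("g2", base2),
        "g3|x": ("g3", random_protein(rng, 90)),
    }
    fams = clustering.build_protein_families(proteins)
    members = sorted(g for f in fams for g in f.gene_ids)
    assert members == sorted(proteins)
    by_gene = {g: f.family_id for f in fams for g in f.gene_ids}
    assert by_gene["g1|a"] == by_gene["g2|a"] == by_gene["g3|a"]
    assert by_gene["g1|b"] == by_gene["g2|b"] != by_gene["g1|a"]
    assert by_gene["g3|x"] not in (by_gene["g1|a"], by_gene["g1|b"])


# --------------------------------------------------------------------------
# Orthologous prophage clustering
# --------------------------------------------------------------------------

def test_content_similarity_values():
    assert clustering.prophage_content_similarity({"a", "b"}, {"a", "b"}) == 1.0
    assert clustering.prophage_content_similarity({"a"}, {"b"}) == 0.0
    assert clustering.prophage_content_similarity(set(), set()) is None
    assert clustering.prophage_content_similarity({"a", "b", "c"}, {"a", "b", "d"}) == pytest.approx(0.5)


def test_threshold_is_strict_jaccard_070_not_merged():
    # |A∩B| = 7, |A∪B| = 10 -> Jaccard exactly 0.70: must stay separate
    shared = {f"f{i}" for i in range(7)}
    fams = {"p1": shared | {"x1", "x2"}, "p2": shared | {"y1"}}
    assert clustering.prophage_content_similarity(fams["p1"], fams["p2"]) == pytest.approx(0.7)
    entities = clustering.cluster_orthologous_prophages(
        fams, {"p1": True, "p2": True}, threshold=0.7
    )
    assert [e.member_prophages for e in entities] == [["p1"], ["p2"]]


def test_jaccard_just_above_070_merged():
    shared = {f"f{i}" for i in range(8)}  # 8/10 = 0.8 > 0.7
    fams = {"p1": shared | {"x1"}, "p2": shared | {"y1"}}
    entities = clustering.cluster_orthologous_prophages(
        fams, {"p1": True, "p2": True}, threshold=0.7
    )
    assert [e.member_prophages for e in entities] == [["p1", "p2"]]


def test_single_linkage_chains_transitively():
    # p1~p2 and p2~p3 above threshold, p1~p3 below: all merged anyway
    fams = {
        "p1": {f"a{i}" for i in range(10)},
        "p2": {f"a{i}" for i in range(8)} | {"b0", "b1"},
        "p3": {"b0", "b1"} | {f"c{i}" for i in range(2)},
    }
    s12 = clustering.prophage_content_similarity(fams["p1"], fams["p2"])
    s23 = clustering.prophage_content_similarity(fams["p2"], fams["p3"])
    s13 = clustering.prophage_content_similarity(fams["p1"], fams["p3"])
    thr = 0.15
    assert s12 > thr and s23 > thr and s13 <= thr, (s12, s23, s13)
    entities = clustering.cluster_orthologous_prophages(
        fams, {p: True for p in fams}, threshold=thr
    )
    assert [e.member_prophages for e in entities] == [["p1", "p2", "p3"]]


def test_phage_only_prophages_excluded():
    fams = {"p1": {"a"}, "p2": {"a"}}
    entities = clustering.cluster_orthologous_prophages(
        fams, {"p1": True, "p2": False}, threshold=0.7
    )
    assert [e.member_prophages for e in entities] == [["p1"]]


def test_singleton_entities_flagged():
    fams = {"p1": {"a"}, "p2": {"b"}}
    entities = clustering.cluster_orthologous_prophages(
        fams, {"p1": True, "p2": True}, threshold=0.7
    )
    assert all(e.is_singleton for e in entities)


def test_hypergeometric_metric():
    a = {f"f{i}" for i in range(5)}
    sim = clustering.hypergeometric_content_similarity(a, a, n_total=100)
    assert sim > 5.0
    assert clustering.hypergeometric_content_similarity({"x"}, {"y"}, 100) == 0.0
    with pytest.raises(ValueError):
        clustering.cluster_orthologous_prophages(
            {"p1": a, "p2": a}, {"p1": True, "p2": True}, metric="hypergeometric"
        )
    with pytest.raises(ValueError):
        clustering.cluster_orthologous_prophages(
            {"p1": a, "p2": a}, {"p1": True, "p2": True}, metric="cosine"
        )
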