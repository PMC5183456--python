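import itertools

import dendropy
import numpy as np
import pytest

from phagelgt import donors, trees
from phagelgt.datatypes import Gene

from conftest import random_protein


def make_gene(gene_id, genome_id, protein, in_prophage=False, gene_class=None):
    return Gene(
        gene_id=gene_id, genome_id=genome_id, start=0, end=3 * len(protein),
        nt="", protein=protein, in_prophage=in_prophage, gene_class=gene_class,
    )


def mutate(base: str, positions, to="W", alt="Y") -> str:
    out = list(base)
    for p in positions:
        out[p] = to if out[p] != to else alt
    return "".join(out)


# --------------------------------------------------------------------------
# Distances
# --------------------------------------------------------------------------

def test_poisson_distance_values():
    d, ok = trees.protein_distance_matrix(["AAAA", "AAAW"])
    assert ok
    assert d[0, 1] == pytest.approx(-np.log(1 - 0.25))
    assert d[0, 0] == 0.0


def test_poisson_saturation_falls_back_to_p_distance():
    d, ok = trees.protein_distance_matrix(["AAAA", "WWWW"])
    assert not ok
    assert d[0, 1] == 1.0


def test_unaligned_lengths_rejected():
    with pytest.raises(ValueError):
        trees.protein_distance_matrix(["AAA", "AAAA"])


# --------------------------------------------------------------------------
# Neighbor joining: exact recovery of an additive tree
# --------------------------------------------------------------------------

def additive_matrix_and_splits():
    """Distances generated from the tree ((a:2,b:3):1,(c:4,d:5):1) — additive,
    so NJ must recover the topology {ab | cd} exactly."""
    labels = ["a", "b", "c", "d"]
    bl = {"a": 2.0, "b": 3.0, "c": 4.0, "d": 5.0}
    inner = 2.0  # a/b side to c/d side through the internal edge
    d = np.zeros((4, 4))
    for i, x in enumerate(labels):
        for j, y in enumerate(labels):
            if i == j:
                continue
            same = {x, y} <= {"a", "b"} or {x, y} <= {"c", "d"}
            d[i, j] = bl[x] + bl[y] + (0.0 if same else inner)
    return labels, d


def unrooted_splits(tree: dendropy.Tree) -> set[frozenset]:
    tree.encode_bipartitions()
    all_taxa = frozenset(t.label for t in tree.taxon_namespace)
    out = set()
    for edge in tree.preorder_edge_iter():
        if edge.head_node and not edge.head_node.is_leaf() and edge.tail_node:
            side = frozenset(trees.leaf_labels(edge.head_node))
            if 1 < len(side) < len(all_taxa) - 1:
                out.add(min(side, all_taxa - side, key=sorted))
    return out


def test_nj_recovers_additive_topology_and_lengths():
    labels, d = additive_matrix_and_splits()
    tree = trees.nj_tree(d, labels)
    assert unrooted_splits(tree) == {frozenset({"a", "b"})}
    # additive distances are reproduced exactly by the NJ tree
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    for i, x in enumerate(labels):
        for y in labels[i + 1:]:
            assert pdm.distance(taxa[x], taxa[y]) == pytest.approx(
                d[labels.index(x)][labels.index(y)]
            )


def test_nj_five_taxon_caterpillar():
    # tree (((a,b),c),d) plus e far away; additive matrix built from it
    src = trees.parse_newick("((((a:1,b:1):1,c:2):1,d:3):1,e:4);")
    pdm = src.phylogenetic_distance_matrix()
    taxa = sorted(src.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.distance(taxa[i], taxa[j])
    rebuilt = trees.nj_tree(d, labels)
    assert unrooted_splits(rebuilt) == unrooted_splits(src)


def test_nj_two_and_one_taxa():
    t2 = trees.nj_tree(np.array([[0.0, 4.0], [4.0, 0.0]]), ["a", "b"])
    assert {lf.taxon.label for lf in t2.leaf_node_iter()} == {"a", "b"}
    t1 = trees.nj_tree(np.zeros((1, 1)), ["a"])
    assert [lf.taxon.label for lf in t1.leaf_node_iter()] == ["a"]


def test_constrained_nj_forces_clade():
    labels, d = additive_matrix_and_splits()
    # force {a, c} together even though the data say {a, b}
    tree = trees.constrained_nj_tree(d, labels, {"a", "c"})
    tree = trees.midpoint_root(tree)
    assert trees.test_recipient_monophyly(tree, {"a", "c"})


# --------------------------------------------------------------------------
# Midpoint rooting
# --------------------------------------------------------------------------

def test_midpoint_root_oracle():
    # longest path d-e has length 9 (4 + 1 + 4); the midpoint sits 0.5 into
    # the internal edge, so the root splits {e} vs the rest
    tree = trees.parse_newick("((((a:1,b:1):1,c:2):1,d:4):1,e:4);")
    rooted = trees.midpoint_root(tree)
    kids = rooted.seed_node.child_nodes()
    sides = sorted(sorted(trees.leaf_labels(k)) for k in kids)
    assert sides == [["a", "b", "c", "d"], ["e"]]
    # the two deepest leaves are equidistant from the root (4.5)
    depths = {lf.taxon.label: lf.distance_from_root() for lf in rooted.leaf_node_iter()}
    assert max(depths.values()) == pytest.approx(4.5)
    assert depths["d"] == pytest.approx(4.5)
    assert depths["e"] == pytest.approx(4.5)


def test_midpoint_root_zero_lengths_is_deterministic():
    a = trees.midpoint_root(trees.parse_newick("((a:0,b:0):0,c:0);"))
    b = trees.midpoint_root(trees.parse_newick("((a:0,b:0):0,c:0);"))
    assert trees.to_newick(a) == trees.to_newick(b)


# --------------------------------------------------------------------------
# Monophyly and sister group
# --------------------------------------------------------------------------

def test_monophyly_and_sisters():
    # tree is rooted as written; midpoint rooting is tested separately
    tree = trees.parse_newick("(((r1:1,r2:1):1,x:2):1,(y:1,z:1):2);")
    assert trees.test_recipient_monophyly(tree, {"r1", "r2"})
    assert not trees.test_recipient_monophyly(tree, {"r1", "x"})
    assert trees.sister_leaves(tree, {"r1", "r2"}) == {"x"}
    assert trees.test_recipient_monophyly(tree, {"y"})
    assert trees.sister_leaves(tree, {"y"}) == {"z"}
    with pytest.raises(ValueError):
        trees.test_recipient_monophyly(tree, set())
    with pytest.raises(ValueError):
        trees.sister_leaves(tree, {"r1", "x"})


# --------------------------------------------------------------------------
# Consolidation test (RELL)
# --------------------------------------------------------------------------

def test_consolidation_accepts_weak_conflict(rng):
    # one site supports q+r2, one supports q+d1 and one supports r2+d1: the
    # constrained and unconstrained trees explain the data equally well
    base = random_protein(rng, 120)
    seqs = {
        "q": mutate(base, [0, 2]),
        "r2": mutate(base, [1, 2]),
        "d1": mutate(base, [0, 1]),
        "o1": mutate(base, range(30, 60)),
        "o2": mutate(base, range(55, 85)),
    }
    labels = sorted(seqs)
    dist, ok = trees.protein_distance_matrix([seqs[x] for x in labels])
    assert ok
    tree = trees.midpoint_root(trees.nj_tree(dist, labels))
    res = trees.consolidation_test(seqs, tree, {"q", "r2"}, dist, labels, seed=1)
    assert res.accepted
    assert res.p_value >= 0.05
    assert trees.test_recipient_monophyly(res.constrained_tree, {"q", "r2"})


def test_consolidation_rejects_strong_conflict(rng):
    # the two "recipients" sit on opposite sides of a deep split supported by
    # many sites: forcing them together must be rejected
    base = random_protein(rng, 200)
    far = mutate(base, range(100))
    seqs = {
        "q": mutate(base, [0]),
        "a1": mutate(base, [1]),
        "a2": mutate(base, [2]),
        "r2": mutate(far, [0]),
        "b1": mutate(far, [1]),
        "b2": mutate(far, [2]),
    }
    labels = sorted(seqs)
    dist, ok = trees.protein_distance_matrix([seqs[x] for x in labels])
    assert ok
    tree = trees.midpoint_root(trees.nj_tree(dist, labels))
    assert not trees.test_recipient_monophyly(tree, {"q", "r2"})
    res = trees.consolidation_test(seqs, tree, {"q", "r2"}, dist, labels, seed=1)
    assert not res.accepted
    assert res.p_value < 0.05
    assert res.delta_lnl < 0


def test_consolidation_deterministic(rng):
    base = random_protein(rng, 80)
    seqs = {
        "q": mutate(base, [0]), "r2": mutate(base, [5]),
        "d": mutate(base, range(10)), "o": mutate(base, range(20, 40)),
    }
    labels = sorted(seqs)
    dist, _ = trees.protein_distance_matrix([seqs[x] for x in labels])
    tree = trees.midpoint_root(trees.nj_tree(dist, labels))
    r1 = trees.consolidation_test(seqs, tree, {"q", "r2"}, dist, labels, seed=4)
    r2 = trees.consolidation_test(seqs, tree, {"q", "r2"}, dist, labels, seed=4)
    assert (r1.accepted, r1.p_value, r1.delta_lnl) == (r2.accepted, r2.p_value, r2.delta_lnl)


# --------------------------------------------------------------------------
# Homolog families
# --------------------------------------------------------------------------

def test_homolog_threshold_900_inclusive(rng):
    base = random_protein(rng, 1000)
    query = make_gene("gR|q", "gR", base)
    candidates = {
        # exactly 90.0%: 100 mismatches out of 1000 -> included
        "g1|at": make_gene("g1|at", "g1", mutate(base, range(100))),
        # 89.9%: 101 mismatches -> excluded
        "g2|below": make_gene("g2|below", "g2", mutate(base, range(101))),
    }
    fam = donors.build_homolog_family(query, candidates, similarity_threshold=90.0)
    assert set(fam.members) == {"gR|q", "g1|at"}
    assert fam.identities["g1|at"] == pytest.approx(90.0)


def test_homolog_family_empty_query_rejected():
    with pytest.raises(ValueError):
        donors.build_homolog_family(make_gene("q", "g", ""), {})


# --------------------------------------------------------------------------
# Donor calling
# --------------------------------------------------------------------------

def is_prophage_copy(gene: Gene) -> bool:
    return gene.in_prophage


def test_call_donor_no_homolog():
    q = make_gene("gR|q", "gR", "ACDEFGHIKL", in_prophage=True)
    fam = donors.HomologFamily("gR|q", {"gR|q": q}, {"gR|q": 100.0})
    call = donors.call_donor(fam, is_prophage_copy)
    assert call.donor is None and call.exclusion_reason == "no_homolog"


def test_call_donor_pair_family(rng):
    base = random_protein(rng, 60)
    q = make_gene("gR|q", "gR", base, in_prophage=True)
    d = make_gene("gD|d", "gD", mutate(base, [0]))
    fam = donors.HomologFamily("gR|q", {"gR|q": q, "gD|d": d},
                               {"gR|q": 100.0, "gD|d": 98.3})
    call = donors.call_donor(fam, is_prophage_copy)
    assert call.donor == "gD" and call.exclusion_reason == "none"
    assert call.donor_gene_id == "gD|d"


def test_call_donor_sister_resolution(rng):
    # query sits inside the donor's diversity: sister = donor genome
    base = random_protein(rng, 150)
    members = {
        "gR|q": make_gene("gR|q", "gR", mutate(base, [0]), in_prophage=True),
        "gD|d": make_gene("gD|d", "gD", mutate(base, [1])),
        "gX|far": make_gene("gX|far", "gX", mutate(base, range(30))),
        "gY|far": make_gene("gY|far", "gY", mutate(base, range(25, 60))),
    }
    idents = {gid: donors.seqsim.global_align_identity(base, g.protein)
              for gid, g in members.items()}
    fam = donors.HomologFamily("gR|q", members, idents)
    call = donors.call_donor(fam, is_prophage_copy)
    assert call.donor == "gD"
    assert call.donor_gene_id == "gD|d"
    assert call.family_size == 4


def test_call_donor_ambiguous_sister_excluded(rng):
    # sister clade mixes two genomes -> donor_clade exclusion
    base = random_protein(rng, 150)
    members = {
        "gR|q": make_gene("gR|q", "gR", mutate(base, [0]), in_prophage=True),
        "gD|d": make_gene("gD|d", "gD", mutate(base, [1])),
        "gE|e": make_gene("gE|e", "gE", mutate(base, [2])),
        "gX|far": make_gene("gX|far", "gX", mutate(base, range(40))),
    }
    idents = {gid: donors.seqsim.global_align_identity(base, g.protein)
              for gid, g in members.items()}
    fam = donors.HomologFamily("gR|q", members, idents)
    call = donors.call_donor(fam, is_prophage_copy)
    assert call.donor is None
    assert call.exclusion_reason == "donor_clade"


def test_call_donor_multi_recipient_excluded(rng):
    base = random_protein(rng, 150)
    members = {
        "gR|q": make_gene("gR|q", "gR", mutate(base, [0]), in_prophage=True),
        "gS|p": make_gene("gS|p", "gS", mutate(base, [1]), in_prophage=True),
        "gD|d": make_gene("gD|d", "gD", mutate(base, [2, 3])),
        "gX|far": make_gene("gX|far", "gX", mutate(base, range(40))),
    }
    idents = {gid: donors.seqsim.global_align_identity(base, g.protein)
              for gid, g in members.items()}
    fam = donors.HomologFamily("gR|q", members, idents)
    call = donors.call_donor(fam, is_prophage_copy)
    assert call.donor is None
    assert call.exclusion_reason == "recipient_clade"


def test_infer_donors_on_simulated_dataset(small_dataset):
    dataset, ledger = small_dataset
    calls = donors.infer_donors(dataset)
    by_gene = {c.gene_id: c for c in calls}
    truth = {e.gene_id: e for e in ledger.events}
    assert set(by_gene) == set(truth)
    called = [g for g, c in by_gene.items() if c.donor is not None]
    correct = sum(1 for g in called if by_gene[g].donor == truth[g].donor)
    assert called, "no donors called at all"
    assert correct / len(called) >= 0.8
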