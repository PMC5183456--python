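"""The directed bipartite transduction (dLGT) network.

Bacteria and phage-entity nodes; donor->phage edges (D class, gene uptake
during lytic infection) and phage->recipient edges (R class, gene acquisition
via lysogeny); integer edge weights count transferred genes. Autologs are
events whose donor genome equals the recipient genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .datatypes import TransductionEvent

BACTERIA = "bacteria"
PHAGE = "phage"

RANK_ORDER = ("species", "genus", "family", "order", "class", "phylum", "domain")


def build_dlgt(events: list[TransductionEvent]) -> nx.DiGraph:
    """Assemble the bipartite dLGT network from transduction events.

    Every event adds weight 1 to the phage->recipient (R) edge; events with a
    resolved donor also add weight 1 to the donor->phage (D) edge. Node names
    carry a ``kind`` attribute; order of events does not affect the result.
    """
    net = nx.DiGraph()
    for ev in sorted(events, key=lambda e: e.gene_id):
        if not ev.recipient or not ev.phage_entity:
            raise ValueError(f"event {ev.gene_id} has dangling references")
        net.add_node(ev.recipient, kind=BACTERIA)
        net.add_node(ev.phage_entity, kind=PHAGE)
        _bump(net, ev.phage_entity, ev.recipient, "R")
        if ev.donor is not None:
            net.add_node(ev.donor, kind=BACTERIA)
            _bump(net, ev.donor, ev.phage_entity, "D")
    return net


def _bump(net: nx.DiGraph, u: str, v: str, klass: str) -> None:
    if net.has_edge(u, v):
        net[u][v]["weight"] += 1
    else:
        net.add_edge(u, v, weight=1, direction_class=klass)


def subset_edges(net: nx.DiGraph, subset: str) -> list[tuple[str, str, dict]]:
    """Edges of the D or R subset (or 'full')."""
    if subset == "full":
        return list(net.edges(data=True))
    if subset not in ("D", "R"):
        raise ValueError("subset must be 'D', 'R' or 'full'")
    return [(u, v, d) for u, v, d in net.edges(data=True)
            if d["direction_class"] == subset]


@dataclass
class AutologSummary:
    n_events: int
    n_autologs: int
    autolog_fraction: float
    genomes_with_autologs: int
    max_genes_per_genome: int
    phages_per_self_recipient: dict[str, int] = field(default_factory=dict)


def detect_autologs(events: list[TransductionEvent]) -> AutologSummary:
    """Annotate events in place and summarize autology (donor == recipient)."""
    per_genome: dict[str, int] = {}
    phages: dict[str, set[str]] = {}
    n_auto = 0
    for ev in events:
        ev.is_autolog = ev.donor is not None and ev.donor == ev.recipient
        if ev.is_autolog:
            n_auto += 1
            per_genome[ev.recipient] = per_genome.get(ev.recipient, 0) + 1
            phages.setdefault(ev.recipient, set()).add(ev.phage_entity)
    return AutologSummary(
        n_events=len(events),
        n_autologs=n_auto,
        autolog_fraction=n_auto / len(events) if events else 0.0,
        genomes_with_autologs=len(per_genome),
        max_genes_per_genome=max(per_genome.values()) if per_genome else 0,
        phages_per_self_recipient={g: len(p) for g, p in sorted(phages.items())},
    )


@dataclass
class NetworkStats:
    subset: str
    n_bacteria: int
    n_phages: int
    n_edges: int
    degrees: dict[str, tuple[int, int]]          # node -> (in, out)
    component_sizes: list[int]                   # weakly connected, descending
    edge_weights: list[int]
    largest_component: int


def component_and_degree_stats(net: nx.DiGraph, subset: str = "full") -> NetworkStats:
    """Degree distributions, weak components and edge weights of a subset."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    edges = subset_edges(net, subset)
    sub = nx.DiGraph()
    for u, v, d in edges:
        sub.add_node(u, **net.nodes[u])
        sub.add_node(v, **net.nodes[v])
        sub.add_edge(u, v, **d)
    comps = sorted((len(c) for c in nx.weakly_connected_components(sub)), reverse=True)
    degrees = {n: (sub.in_degree(n), sub.out_degree(n)) for n in sorted(sub.nodes)}
    kinds = nx.get_node_attributes(sub, "kind")
    return NetworkStats(
        subset=subset,
        n_bacteria=sum(1 for n in sub.nodes if kinds[n] == BACTERIA),
        n_phages=sum(1 for n in sub.nodes if kinds[n] == PHAGE),
        n_edges=sub.number_of_edges(),
        degrees=degrees,
        component_sizes=comps,
        edge_weights=sorted(d["weight"] for _, _, d in edges),
        largest_component=comps[0] if comps else 0,
    )


def compare_degree_distributions(a: list[int], b: list[int]) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov comparison of degree (or weight) samples."""
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# Host range
# --------------------------------------------------------------------------

def deepest_shared_rank(taxa: list[dict[str, str]]) -> str:
    """Lowest taxonomic rank whose label is shared by all entries.

    Entries missing a rank are compared at the lowest rank they all carry.
    """
    for rank in RANK_ORDER:
        labels = {t.get(rank) for t in taxa}
        if None in labels:
            continue
        if len(labels) == 1:
            return rank
    return "unclassified"


@dataclass
class HostRangeReport:
    donor_rank_counts: dict[str, int]
    recipient_rank_counts: dict[str, int]
    per_phage_donor_rank: dict[str, str]
    per_phage_recipient_rank: dict[str, str]
    donor_recipient_rank_counts: dict[str, int]  # per-event donor vs recipient rank


def host_range_taxonomy(
    net: nx.DiGraph,
    events: list[TransductionEvent],
    taxonomy: dict[str, dict[str, str]],
) -> HostRangeReport:
    """Taxonomic host-range of each phage and of donor–recipient pairs."""
    donors: dict[str, set[str]] = {}
    recipients: dict[str, set[str]] = {}
    for u, v, d in net.edges(data=True):
        if d["direction_class"] == "D":
            donors.setdefault(v, set()).add(u)
        else:
            recipients.setdefault(u, set()).add(v)
    per_d, per_r = {}, {}
    d_counts: dict[str, int] = {}
    r_counts: dict[str, int] = {}
    for phage in sorted(set(donors) | set(recipients)):
        ds = sorted(donors.get(phage, ()))
        rs = sorted(recipients.get(phage, ()))
        if len(ds) >= 2:
            rank = deepest_shared_rank([taxonomy[g] for g in ds])
            per_d[phage] = rank
            d_counts[rank] = d_counts.get(rank, 0) + 1
        if len(rs) >= 2:
            rank = deepest_shared_rank([taxonomy[g] for g in rs])
            per_r[phage] = rank
            r_counts[rank] = r_counts.get(rank, 0) + 1
    dr_counts: dict[str, int] = {}
    for ev in events:
        if ev.donor is None:
            continue
        rank = deepest_shared_rank([taxonomy[ev.donor], taxonomy[ev.recipient]])
        dr_counts[rank] = dr_counts.get(rank, 0) + 1
    return HostRangeReport(
        donor_rank_counts=dict(sorted(d_counts.items())),
        recipient_rank_counts=dict(sorted(r_counts.items())),
        per_phage_donor_rank=per_d,
        per_phage_recipient_rank=per_r,
        donor_recipient_rank_counts=dict(sorted(dr_counts.items())),
    )


# --------------------------------------------------------------------------
# Projections, aggregation and export
# --------------------------------------------------------------------------

def donor_recipient_pairs(net: nx.DiGraph) -> set[tuple[str, str]]:
    """Distinct donor->recipient pairs connected through a phage."""
    pairs = set()
    for phage in (n for n, d in net.nodes(data=True) if d["kind"] == PHAGE):
        ds = [u for u, _, d in net.in_edges(phage, data=True) if d["direction_class"] == "D"]
        rs = [v for _, v, d in net.out_edges(phage, data=True) if d["direction_class"] == "R"]
        for u in ds:
            for v in rs:
                pairs.add((u, v))
    return pairs


def unipartite_projection(net: nx.DiGraph) -> nx.DiGraph:
    """Donor->recipient projection (autologs become self-loops)."""
    proj = nx.DiGraph()
    for u, v in sorted(donor_recipient_pairs(net)):
        if proj.has_edge(u, v):
            proj[u][v]["weight"] += 1
        else:
            proj.add_edge(u, v, weight=1)
    return proj


def aggregate_by_rank(
    net: nx.DiGraph, taxonomy: dict[str, dict[str, str]], rank: str = "species"
) -> nx.DiGraph:
    """Collapse bacteria nodes by a taxonomy rank (phage nodes unchanged)."""
    agg = nx.DiGraph()
    def name(n):
        if net.nodes[n]["kind"] == BACTERIA:
            return taxonomy[n].get(rank, n)
        return n
    for u, v, d in net.edges(data=True):
        au, av = name(u), name(v)
        agg.add_node(au, kind=net.nodes[u]["kind"])
        agg.add_node(av, kind=net.nodes[v]["kind"])
        if agg.has_edge(au, av):
            agg[au][av]["weight"] += d["weight"]
        else:
            agg.add_edge(au, av, weight=d["weight"], direction_class=d["direction_class"])
    return agg


def edge_table(net: nx.DiGraph) -> list[tuple[str, str, str, int]]:
    """Sorted (source, target, direction_class, weight) rows for TSV export."""
    return sorted(
        (u, v, d["direction_class"], d["weight"]) for u, v, d in net.edges(data=True)
    )


def total_weight(net: nx.DiGraph, subset: str) -> int:
    return sum(d["weight"] for _, _, d in subset_edges(net, subset))


def degree_preservation_check(original: nx.DiGraph, randomized: nx.DiGraph) -> bool:
    """True iff every node keeps its in/out degree and the edge-weight multiset
    is preserved within each direction class."""
    if set(original.nodes) != set(randomized.nodes):
        return False
    for n in original.nodes:
        if original.in_degree(n) != randomized.in_degree(n):
            return False
        if original.out_degree(n) != randomized.out_degree(n):
            return False
    for subset in ("D", "R"):
        wa = sorted(d["weight"] for _, _, d in subset_edges(original, subset))
        wb = sorted(d["weight"] for _, _, d in subset_edges(randomized, subset))
        if wa != wb:
            return False
    return True
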