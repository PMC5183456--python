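"""Degree-preserving null models for the dLGT network.

The switching method: repeated double-edge swaps within each direction class
(two donor->phage edges (a->p, b->q) become (a->q, b->p), likewise for
phage->recipient edges). Swaps that would duplicate an existing edge are
rejected. Each edge keeps its weight, so every node's in/out degree, every
node's out-strength and the per-class edge-weight multiset are conserved
exactly; in-strengths are shuffled among nodes of equal in-degree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator

import networkx as nx
import numpy as np

from .network import subset_edges


def switch_randomize(
    net: nx.DiGraph,
    n_swaps: int | None = None,
    seed: int | np.random.Generator = 0,
    swaps_per_edge: float = 100.0,
) -> nx.DiGraph:
    """One degree-preserving rewiring of the network.

    ``n_swaps`` attempted swaps are split between the D and R edge classes in
    proportion to their sizes (default ``swaps_per_edge`` per edge). A class
    with fewer than 2 edges is returned unchanged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = nx.DiGraph()
    out.add_nodes_from(net.nodes(data=True))
    for klass in ("D", "R"):
        edges = subset_edges(net, klass)
        m = len(edges)
        attempts = int(round((n_swaps if n_swaps is not None else swaps_per_edge * m)
                             * (1.0 if n_swaps is None else m / max(net.number_of_edges(), 1))))
        src = [u for u, _, _ in edges]
        dst = [v for _, v, _ in edges]
        wts = [d["weight"] for _, _, d in edges]
        if m >= 2 and attempts > 0:
            existing = set(zip(src, dst))
            pairs = rng.integers(0, m, size=(attempts, 2))
            for i, j in pairs:
                if i == j:
                    continue
                a, p = src[i], dst[i]
                b, q = src[j], dst[j]
                if p == q or a == b:
                    continue
                if (a, q) in existing or (b, p) in existing:
                    continue
                existing.discard((a, p))
                existing.discard((b, q))
                existing.add((a, q))
                existing.add((b, p))
                dst[i], dst[j] = q, p
        for u, v, w in zip(src, dst, wts):
            out.add_edge(u, v, weight=w, direction_class=klass)
    return out


@dataclass
class NullEnsemble:
    n_replicates: int
    seed: int
    statistics: dict[str, np.ndarray]  # statistic name -> per-replicate values


def build_ensemble(
    net: nx.DiGraph,
    statistics: dict[str, Callable[[nx.DiGraph], float]],
    n_replicates: int = 1000,
    swaps_per_edge: float = 100.0,
    seed: int = 0,
) -> NullEnsemble:
    """Per-replicate summary statistics over independent rewirings.

    ``statistics`` maps names to functions of a rewired network; storing
    summaries rather than replicates keeps 1000-network ensembles cheap.
    Reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    values: dict[str, list[float]] = {name: [] for name in statistics}
    for _ in range(n_replicates):
        rand = switch_randomize(net, seed=rng, swaps_per_edge=swaps_per_edge)
        for name, fn in statistics.items():
            values[name].append(fn(rand))
    return NullEnsemble(
        n_replicates=n_replicates,
        seed=seed,
        statistics={k: np.asarray(v) for k, v in values.items()},
    )


def iter_randomized(
    net: nx.DiGraph,
    n_replicates: int,
    swaps_per_edge: float = 100.0,
    seed: int = 0,
) -> Iterator[nx.DiGraph]:
    """Yield rewired replicates one at a time (reproducible under seed)."""
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        yield switch_randomize(net, seed=rng, swaps_per_edge=swaps_per_edge)


def empirical_pvalue(
    observed: float, null_values: np.ndarray | list[float], tail: str = "upper"
) -> float:
    """Empirical p-value (r + 1) / (n + 1) with r the number of null values at
    least as extreme as the observation."""
    nulls = np.asarray(null_values, dtype=float)
    if nulls.size == 0:
        raise ValueError("need at least one null value")
    if tail == "upper":
        r = int(np.sum(nulls >= observed))
    elif tail == "lower":
        r = int(np.sum(nulls <= observed))
    elif tail == "two":
        med = np.median(nulls)
        r = int(np.sum(np.abs(nulls - med) >= abs(observed - med)))
    else:
        raise ValueError("tail must be 'upper', 'lower' or 'two'")
    return (r + 1) / (nulls.size + 1)
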