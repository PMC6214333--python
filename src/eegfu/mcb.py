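"""Maximal-clique-based (MCB) functional-unit detection.

Enumerates the cliques of the significant coherence graph that are
Voronoi-connected and maximal *within the family of Voronoi-connected
cliques* (a returned set may be a strict subset of a larger, spatially
disconnected clique).  Shared vertices are then assigned uniquely to the
clique of largest total strength.

The enumeration is a Bron-Kerbosch-style recursion with a spatial
frontier: candidates connected to the whole growing clique ``compsub``
are split into ``currentcand`` (Voronoi-adjacent to at least one member,
hence addable now) and ``complcand`` (reachable only after the frontier
grows toward them).  The ``not`` set of previously used vertices is
split the same way: a previously used vertex suppresses reporting only
while it is Voronoi-adjacent to the growing clique, since only then
would it extend ``compsub`` within the Voronoi-connected family.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np

from .model import (
    CoherenceNetwork,
    Partition,
    SpatialAdjacency,
    is_voronoi_connected,
    significant_graph,
)

__all__ = [
    "enumerate_spatial_maximal_cliques",
    "total_strength",
    "mcb_detect",
]


def _select(
    pool: set[str],
    candidates: set[str],
    neighbors: dict[str, set[str]],
    rng: np.random.Generator | None,
) -> str:
    """Element of ``pool`` with the most graph connections to ``candidates``.

    Ties go to the lowest label by default, or to a uniformly random
    tied element when ``rng`` is given (the paper's randomized rule).
    """
    best = max(len(neighbors[v] & candidates) for v in pool)
    tied = sorted(v for v in pool if len(neighbors[v] & candidates) == best)
    if rng is not None and len(tied) > 1:
        return tied[rng.integers(len(tied))]
    return tied[0]


def enumerate_spatial_maximal_cliques(
    graph: nx.Graph,
    adjacency: SpatialAdjacency,
    *,
    rng: np.random.Generator | None = None,
) -> set[frozenset[str]]:
    """All Voronoi-connected cliques of ``graph`` that are maximal within
    the Voronoi-connected-clique family (singletons included).

    ``rng`` switches candidate tie-breaking from lowest-label to seeded
    random selection; the returned *set* of cliques is the same either
    way, only the traversal order changes.
    """
    N = {v: set(graph.adj[v]) for v in graph.nodes}
    VN = {v: set(adjacency.neighbors(v)) for v in graph.nodes}
    results: set[frozenset[str]] = set()

    def extend(
        compsub: list[str],
        currentcand: set[str],
        complcand: set[str],
        not_vor: set[str],
        not_far: set[str],
    ) -> None:
        if not currentcand:
            if not not_vor:
                results.add(frozenset(compsub))
            return
        currentcand = set(currentcand)
        not_vor = set(not_vor)
        not_far = set(not_far)
        while currentcand:
            v = _select(currentcand, currentcand | complcand, N, rng)
            currentcand.discard(v)
            nb = N[v]
            lam = {u for u in complcand if u in nb and u in VN[v]}
            promoted = {u for u in not_far if u in nb and u in VN[v]}
            extend(
                compsub + [v],
                (currentcand & nb) | lam,
                (complcand & nb) - lam,
                (not_vor & nb) | promoted,
                (not_far & nb) - promoted,
            )
            not_vor.add(v)  # v is Voronoi-adjacent to compsub's frontier via itself

    # Root: compsub is empty, so the spatial frontier is defined only
    # after the first vertex is chosen.
    cand = set(graph.nodes)
    not_root: set[str] = set()
    while cand:
        v = _select(cand, cand, N, rng)
        cand.discard(v)
        nb = N[v] & cand
        used = not_root & N[v]
        extend(
            [v],
            {u for u in nb if u in VN[v]},
            {u for u in nb if u not in VN[v]},
            {u for u in used if u in VN[v]},
            {u for u in used if u not in VN[v]},
        )
        not_root.add(v)
    return results


def total_strength(members, graph: nx.Graph) -> float:
    """Sum of significant-edge weights with both endpoints in ``members``."""
    return float(graph.subgraph(members).size(weight="weight"))


def mcb_detect(
    network: CoherenceNetwork,
    adjacency: SpatialAdjacency,
    *,
    rng: np.random.Generator | None = None,
) -> Partition:
    """MCB functional units: enumerate Voronoi-connected maximal cliques,
    then keep each shared vertex only in the clique of largest total
    strength (ties: the clique whose smallest member label sorts first).

    The residual of a clique that loses a shared vertex is kept as an FU
    even if no longer maximal; if the removal spatially disconnects it, a
    warning is emitted (the set is still reported as one FU).
    """
    graph = significant_graph(network)
    cliques = sorted(
        enumerate_spatial_maximal_cliques(graph, adjacency, rng=rng),
        key=lambda q: tuple(sorted(q)),
    )
    strength = {q: total_strength(q, graph) for q in cliques}

    assigned: dict[str, frozenset[str]] = {}
    for v in graph.nodes:
        homes = [q for q in cliques if v in q]
        # largest total strength wins; ties by lexicographically first
        # member tuple (i.e. smallest leading label)
        assigned[v] = min(homes, key=lambda q: (-strength[q], tuple(sorted(q))))

    fus: dict[frozenset[str], set[str]] = {}
    for v, q in assigned.items():
        fus.setdefault(q, set()).add(v)

    for q, members in fus.items():
        if len(members) >= 2 and not is_voronoi_connected(members, adjacency):
            warnings.warn(
                f"FU {sorted(members)} lost shared vertices and is no longer "
                "spatially connected",
                stacklevel=2,
            )
    return Partition(tuple(tuple(sorted(s)) for s in fus.values()))
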