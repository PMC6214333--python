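"""Improved watershed-based (IWB) functional-unit detection.

Markers are electrodes whose local average coherence is a weak maximum
over their Voronoi neighborhood (one marker per equal-value plateau
component, the smallest label).  Each marker seeds a basin; a queue of
significant marker-to-neighbor edges is flooded in descending coherence
order.  A popped edge (v, v') labels v' into v's basin only if v' is
significantly connected to *every* current member of that basin (basins
stay cliques); edges failing the test are discarded, not re-queued.
When v' already carries a different label, the two basins merge iff
their union is a clique of the significant graph.  Unlabeled electrodes
end as singletons.

Queue ties (equal coherence) pop in insertion order, then by the
lexicographic (v, v') of the edge.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass

from .model import (
    CoherenceNetwork,
    Partition,
    SpatialAdjacency,
    local_average_coherence,
    significant_graph,
)

__all__ = ["PopEvent", "detect_markers", "iwb_detect", "iwb_trace"]


@dataclass(frozen=True)
class PopEvent:
    """One dequeued edge and what the flood did with it."""

    edge: tuple[str, str]  # (labeled source v, target v')
    value: float
    action: str  # "label" | "merge" | "merge-failed" | "same-basin" | "discard"


def detect_markers(
    network: CoherenceNetwork, adjacency: SpatialAdjacency
) -> tuple[str, ...]:
    """Electrodes with locally maximal average coherence.

    ``v`` qualifies when its local average coherence is >= that of every
    Voronoi neighbor.  Equal-value plateaus of qualifying, mutually
    Voronoi-adjacent electrodes contribute exactly one marker: the
    smallest label of the plateau component.
    """
    values, _ = local_average_coherence(network, adjacency)
    graph = significant_graph(network)
    # the flood propagates along significant spatial edges only, so the
    # maximum is taken over significantly connected Voronoi neighbors; a
    # vertex with none can seed no basin and is not a marker
    sig_nbrs = {
        v: tuple(u for u in adjacency.neighbors(v) if graph.has_edge(v, u))
        for v in network.layout.labels
    }
    candidates = {
        v
        for v in network.layout.labels
        if sig_nbrs[v] and all(values[v] >= values[u] for u in sig_nbrs[v])
    }
    markers: list[str] = []
    seen: set[str] = set()
    for v in sorted(candidates):
        if v in seen:
            continue
        # flood the equal-value plateau component containing v
        component = {v}
        stack = [v]
        while stack:
            u = stack.pop()
            for w in sig_nbrs[u]:
                if w in candidates and w not in component and values[w] == values[u]:
                    component.add(w)
                    stack.append(w)
        seen.update(component)
        markers.append(min(component))
    return tuple(sorted(markers))


def _run(
    network: CoherenceNetwork, adjacency: SpatialAdjacency
) -> tuple[Partition, list[PopEvent]]:
    graph = significant_graph(network)
    markers = detect_markers(network, adjacency)

    label_of: dict[str, int] = {m: i for i, m in enumerate(markers, start=1)}
    basins: dict[int, set[str]] = {i: {m} for i, m in enumerate(markers, start=1)}

    counter = itertools.count()  # insertion order for tie-breaking
    heap: list[tuple[float, int, str, str]] = []

    def push(v: str, vp: str) -> None:
        c = network.value(v, vp)
        heapq.heappush(heap, (-c, next(counter), v, vp))

    for m in markers:
        for u in sorted(adjacency.neighbors(m)):
            if u not in label_of and graph.has_edge(m, u):
                push(m, u)

    events: list[PopEvent] = []
    while heap:
        neg_c, _, v, vp = heapq.heappop(heap)
        c = -neg_c
        basin_v = label_of[v]
        if vp not in label_of:
            if all(graph.has_edge(vp, w) for w in basins[basin_v]):
                label_of[vp] = basin_v
                basins[basin_v].add(vp)
                for u in sorted(adjacency.neighbors(vp)):
                    if u not in label_of and graph.has_edge(vp, u):
                        push(vp, u)
                events.append(PopEvent((v, vp), c, "label"))
            else:
                events.append(PopEvent((v, vp), c, "discard"))
        elif label_of[vp] != basin_v:
            basin_vp = label_of[vp]
            union = basins[basin_v] | basins[basin_vp]
            if all(
                graph.has_edge(a, b)
                for a in union
                for b in union
                if a < b
            ):
                for w in basins[basin_vp]:
                    label_of[w] = basin_v
                basins[basin_v].update(basins.pop(basin_vp))
                events.append(PopEvent((v, vp), c, "merge"))
            else:
                events.append(PopEvent((v, vp), c, "merge-failed"))
        else:
            events.append(PopEvent((v, vp), c, "same-basin"))

    singletons = [
        (v,) for v in network.layout.labels if v not in label_of
    ]
    communities = tuple(tuple(sorted(b)) for b in basins.values()) + tuple(
        singletons
    )
    return Partition(communities), events


def iwb_detect(
    network: CoherenceNetwork, adjacency: SpatialAdjacency
) -> Partition:
    """Functional units by marker-based watershed flooding (see module
    docstring for the exact rules)."""
    partition, _ = _run(network, adjacency)
    return partition


def iwb_trace(
    network: CoherenceNetwork, adjacency: SpatialAdjacency
) -> tuple[Partition, list[PopEvent]]:
    """Like :func:`iwb_detect`, also returning the dequeue event log."""
    return _run(network, adjacency)
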