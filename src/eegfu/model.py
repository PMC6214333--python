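"""Core data model for EEG coherence networks.

An EEG coherence network couples an electrode layout (a top-view 2D head
projection) with a symmetric matrix of magnitude-squared coherences in
[0, 1].  Spatial structure enters through the Voronoi diagram of the
electrode positions: two electrodes are *Voronoi neighbors* when their
cells share a boundary segment of positive length, and a set of
electrodes is *Voronoi connected* when it induces a connected subgraph
of that neighbor relation.  Thresholding the coherence matrix at the
significance level ``theta`` yields the *significant graph*, the weighted
undirected graph on which all functional-unit detection operates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import QhullError, Voronoi

__all__ = [
    "ElectrodeLayout",
    "SpatialAdjacency",
    "CoherenceNetwork",
    "Partition",
    "voronoi_adjacency",
    "is_voronoi_connected",
    "significance_threshold",
    "significant_graph",
    "local_average_coherence",
]

#: relative tolerance used when validating matrix symmetry
SYMMETRY_ATOL = 1e-12

#: relative ridge-length cutoff below which a Voronoi boundary is treated
#: as degenerate (a point, not a segment) — e.g. diagonal "ridges" produced
#: by cocircular sites on a square grid
RIDGE_LENGTH_RTOL = 1e-9


@dataclass(frozen=True)
class ElectrodeLayout:
    """Electrode labels and their 2D positions (top view, arbitrary units)."""

    labels: tuple[str, ...]
    positions: np.ndarray  # shape (n, 2)

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        if len(labels) != len(pos):
            raise ValueError(
                f"{len(labels)} labels but {len(pos)} positions"
            )
        if len(labels) < 1:
            raise ValueError("layout needs at least one electrode")
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate electrode labels: {dupes}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("electrode positions must be finite")
        # name colliding labels, not just indices
        seen: dict[tuple[float, float], str] = {}
        for lab, p in zip(labels, pos):
            key = (float(p[0]), float(p[1]))
            if key in seen:
                raise ValueError(
                    f"electrodes {seen[key]!r} and {lab!r} share position {key}"
                )
            seen[key] = lab
        object.__setattr__(self, "labels", labels)
        pos.setflags(write=False)
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown electrode label {label!r}") from None

    def position_of(self, label: str) -> np.ndarray:
        return self.positions[self.index(label)]


@dataclass(frozen=True)
class SpatialAdjacency:
    """The Voronoi-neighbor relation over an electrode layout.

    Stored as a set of unordered label pairs; symmetric and irreflexive
    by construction.
    """

    labels: tuple[str, ...]
    pairs: frozenset[frozenset[str]]
    _neighbors: dict[str, tuple[str, ...]] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        known = set(self.labels)
        nbrs: dict[str, set[str]] = {lab: set() for lab in self.labels}
        for pair in self.pairs:
            u, v = sorted(pair)
            if u == v:
                raise ValueError(f"self-pair {u!r} in adjacency")
            if u not in known or v not in known:
                raise ValueError(f"pair ({u!r}, {v!r}) not in layout labels")
            nbrs[u].add(v)
            nbrs[v].add(u)
        object.__setattr__(
            self,
            "_neighbors",
            {lab: tuple(sorted(s)) for lab, s in nbrs.items()},
        )

    def neighbors(self, label: str) -> tuple[str, ...]:
        """Voronoi neighbors of ``label``, in ascending label order."""
        try:
            return self._neighbors[label]
        except KeyError:
            raise KeyError(f"unknown electrode label {label!r}") from None

    def are_neighbors(self, u: str, v: str) -> bool:
        return v in self._neighbors.get(u, ())

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self.are_neighbors(*pair)


@dataclass(frozen=True)
class CoherenceNetwork:
    """Electrode layout + symmetric coherence matrix + threshold theta.

    The matrix carries the coherence ``c(v, v')`` for every electrode
    pair, in [0, 1], with an exactly-zero diagonal (vertices are not
    self-connected).  ``theta`` is the significance threshold applied
    when the significant graph is formed.
    """

    layout: ElectrodeLayout
    coherence: np.ndarray
    theta: float

    def __post_init__(self) -> None:
        mat = np.asarray(self.coherence, dtype=float)
        n = len(self.layout)
        if mat.shape != (n, n):
            raise ValueError(f"coherence matrix must be {n}x{n}, got {mat.shape}")
        if not np.all(np.isfinite(mat)):
            raise ValueError("coherence matrix contains non-finite values")
        if np.max(np.abs(mat - mat.T)) > SYMMETRY_ATOL:
            raise ValueError("coherence matrix is not symmetric within 1e-12")
        if np.any(np.diag(mat) != 0.0):
            raise ValueError("coherence matrix diagonal must be exactly zero")
        if mat.min() < 0.0 or mat.max() > 1.0:
            raise ValueError("coherence values must lie in [0, 1]")
        if not 0.0 <= float(self.theta) <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        mat = (mat + mat.T) / 2.0  # exact symmetry for downstream arithmetic
        np.fill_diagonal(mat, 0.0)
        mat.setflags(write=False)
        object.__setattr__(self, "coherence", mat)
        object.__setattr__(self, "theta", float(self.theta))

    def value(self, u: str, v: str) -> float:
        return float(
            self.coherence[self.layout.index(u), self.layout.index(v)]
        )


@dataclass(frozen=True)
class Partition:
    """A partition of the electrode set into communities / FUs.

    Canonical form: communities are sorted member tuples, ordered by their
    smallest member label; community ids are 1-based in that order.
    """

    communities: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        cleaned = []
        for comm in self.communities:
            members = tuple(sorted(comm))
            if not members:
                continue  # empty communities pruned on read-out
            overlap = seen.intersection(members)
            if overlap:
                raise ValueError(f"labels in multiple communities: {sorted(overlap)}")
            seen.update(members)
            cleaned.append(members)
        cleaned.sort(key=lambda c: c[0])
        object.__setattr__(self, "communities", tuple(cleaned))

    @classmethod
    def from_labels(cls, assignment: dict[str, object]) -> "Partition":
        groups: dict[object, list[str]] = {}
        for lab, comm in assignment.items():
            groups.setdefault(comm, []).append(lab)
        return cls(tuple(tuple(sorted(g)) for g in groups.values()))

    def label_of(self, label: str) -> int:
        """1-based community id containing ``label``."""
        for i, comm in enumerate(self.communities, start=1):
            if label in comm:
                return i
        raise KeyError(f"label {label!r} not in partition")

    def to_assignment(self) -> dict[str, int]:
        return {
            lab: i
            for i, comm in enumerate(self.communities, start=1)
            for lab in comm
        }

    def members(self) -> frozenset[str]:
        return frozenset(itertools.chain.from_iterable(self.communities))

    def multi_member(self) -> tuple[tuple[str, ...], ...]:
        """Communities with at least two members."""
        return tuple(c for c in self.communities if len(c) >= 2)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.communities == other.communities

    def __hash__(self) -> int:
        return hash(self.communities)


# ---------------------------------------------------------------------------
# Voronoi spatial adjacency
# ---------------------------------------------------------------------------

def voronoi_adjacency(layout: ElectrodeLayout) -> SpatialAdjacency:
    """Voronoi-neighbor relation of an electrode layout.

    A pair is adjacent iff their Voronoi cells share a boundary segment
    of positive length.  Degenerate zero-length ridges (e.g. the point
    where four cells of a square grid meet) are excluded, so the unit
    grid yields exactly 4-connectivity.  Collinear layouts fall back to
    the chain of consecutive sites along the line.
    """
    n = len(layout)
    if n < 2:
        raise ValueError("voronoi_adjacency needs at least 2 electrodes")
    pos = layout.positions
    if n == 2:
        pairs = {frozenset(layout.labels)}
        return SpatialAdjacency(layout.labels, frozenset(pairs))

    centered = pos - pos.mean(axis=0)
    scale = float(np.max(np.abs(centered))) or 1.0
    # rank-1 point cloud => all sites collinear; Voronoi cells are slabs
    # between consecutive bisectors => adjacency is the sorted chain
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] <= 1e-12 * max(sv[0], 1.0):
        return _collinear_chain(layout, centered)

    try:
        vor = Voronoi(pos)
    except QhullError:
        return _collinear_chain(layout, centered)

    tol = RIDGE_LENGTH_RTOL * scale
    pairs: set[frozenset[str]] = set()
    for (i, j), ridge in zip(vor.ridge_points, vor.ridge_vertices):
        if -1 in ridge:  # unbounded ridge: always positive length
            pairs.add(frozenset((layout.labels[i], layout.labels[j])))
            continue
        v1, v2 = vor.vertices[ridge[0]], vor.vertices[ridge[1]]
        if np.hypot(*(v1 - v2)) > tol:
            pairs.add(frozenset((layout.labels[i], layout.labels[j])))
    return SpatialAdjacency(layout.labels, frozenset(pairs))


def _collinear_chain(
    layout: ElectrodeLayout, centered: np.ndarray
) -> SpatialAdjacency:
    direction = centered[np.argmax(np.linalg.norm(centered, axis=1))]
    t = centered @ direction
    order = np.argsort(t, kind="stable")
    pairs = {
        frozenset((layout.labels[order[k]], layout.labels[order[k + 1]]))
        for k in range(len(order) - 1)
    }
    return SpatialAdjacency(layout.labels, frozenset(pairs))


def is_voronoi_connected(
    members, adjacency: SpatialAdjacency
) -> bool:
    """True iff ``members`` is empty, a singleton, or induces a connected
    subgraph of the Voronoi-neighbor relation."""
    members = set(members)
    unknown = members.difference(adjacency.labels)
    if unknown:
        raise KeyError(f"unknown electrode labels: {sorted(unknown)}")
    if len(members) <= 1:
        return True
    start = next(iter(members))
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adjacency.neighbors(u):
            if v in members and v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == len(members)


# ---------------------------------------------------------------------------
# Significance threshold and significant graph
# ---------------------------------------------------------------------------

def significance_threshold(p: float, L: int) -> float:
    """Analytic null threshold ``theta = 1 - p**(1/(L-1))``.

    For magnitude-squared coherence averaged over ``L`` independent
    segments, an estimated value exceeds ``theta`` with probability ``p``
    under the hypothesis of independent signals; ``theta`` is thus the
    (1-p) null quantile.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly between 0 and 1")
    if int(L) != L or L < 2:
        raise ValueError("L must be an integer >= 2 (threshold undefined otherwise)")
    return 1.0 - p ** (1.0 / (L - 1))


def significant_graph(network: CoherenceNetwork) -> nx.Graph:
    """Weighted undirected graph of coherences ``>= theta`` (closed).

    Every electrode is a node; isolated electrodes stay isolated nodes.
    """
    G = nx.Graph()
    G.add_nodes_from(network.layout.labels)
    mat = network.coherence
    labels = network.layout.labels
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if mat[i, j] >= network.theta:
                G.add_edge(labels[i], labels[j], weight=float(mat[i, j]))
    return G


# ---------------------------------------------------------------------------
# Local average coherence
# ---------------------------------------------------------------------------

def local_average_coherence(
    network: CoherenceNetwork, adjacency: SpatialAdjacency
) -> tuple[dict[str, float], list[str]]:
    """Per-electrode mean coherence over *all* Voronoi neighbors.

    Sub-threshold coherences are included: the average is a property of
    the raw coherence field, not of the significant graph.  Returns the
    value map and the descending ranking (ties broken by ascending
    label order).
    """
    if set(adjacency.labels) != set(network.layout.labels):
        raise ValueError("network and adjacency must cover the same layout")
    values: dict[str, float] = {}
    for lab in network.layout.labels:
        nbrs = adjacency.neighbors(lab)
        if not nbrs:
            values[lab] = 0.0
        else:
            values[lab] = float(
                np.mean([network.value(lab, u) for u in nbrs])
            )
    ranking = sorted(values, key=lambda lab: (-values[lab], lab))
    return values, ranking
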