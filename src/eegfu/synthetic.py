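"""Fixtures and generators: the 12-node worked example, planted-partition
coherence networks on grids, and coherent multichannel signal simulation.

Everything any pipeline stage needs for testing is generated here in
memory; no external data is required.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

from .model import (
    CoherenceNetwork,
    ElectrodeLayout,
    Partition,
    SpatialAdjacency,
    voronoi_adjacency,
)
from .spectra import SegmentedRecording

__all__ = [
    "grid_layout",
    "fig3_grid_layout",
    "table1_network",
    "montage_10_20",
    "fixture",
    "PlantedNetwork",
    "planted_partition_network",
    "simulate_recording",
]


def grid_layout(
    rows: int, cols: int, labels: tuple[str, ...] | None = None
) -> ElectrodeLayout:
    """Unit grid layout: row r (0 = top), column k at position (k, -r).

    Its Voronoi adjacency is exactly 4-connectivity.  Default labels are
    a, b, c, ... in row-major order when the grid has <= 26 cells, else
    ``r{r}c{k}``.
    """
    n = rows * cols
    if labels is None:
        if n <= 26:
            labels = tuple(string.ascii_lowercase[:n])
        else:
            labels = tuple(f"r{r}c{k}" for r in range(rows) for k in range(cols))
    positions = np.array(
        [(float(k), float(-r)) for r in range(rows) for k in range(cols)]
    )
    return ElectrodeLayout(labels=tuple(labels), positions=positions)


def fig3_grid_layout() -> ElectrodeLayout:
    """The worked example's 3x4 grid: rows [a b c d], [e f g h], [i j k l]."""
    return grid_layout(3, 4)


# Upper triangle of the worked example's 12x12 synthetic coherence matrix;
# every pair not listed here has coherence 0.10.
_TABLE1_UPPER = {
    ("a", "b"): 0.65, ("a", "e"): 0.64, ("a", "f"): 0.60, ("a", "g"): 0.20,
    ("a", "i"): 0.30, ("a", "j"): 0.23,
    ("b", "e"): 0.63, ("b", "f"): 0.63, ("b", "g"): 0.21, ("b", "i"): 0.32,
    ("b", "j"): 0.33,
    ("d", "g"): 0.70, ("d", "h"): 0.71, ("d", "l"): 0.70,
    ("e", "f"): 0.62, ("e", "g"): 0.20, ("e", "i"): 0.33, ("e", "j"): 0.20,
    ("f", "g"): 0.70, ("f", "i"): 0.30, ("f", "j"): 0.31,
    ("g", "h"): 0.69, ("g", "i"): 0.20, ("g", "j"): 0.20, ("g", "l"): 0.70,
    ("h", "l"): 0.72,
    ("i", "j"): 0.32,
}


def table1_network() -> tuple[CoherenceNetwork, SpatialAdjacency]:
    """The 12-node synthetic coherence network of the worked example
    (theta = 0.2) together with its grid Voronoi adjacency."""
    layout = fig3_grid_layout()
    n = len(layout)
    mat = np.full((n, n), 0.10)
    np.fill_diagonal(mat, 0.0)
    for (u, v), c in _TABLE1_UPPER.items():
        i, j = layout.index(u), layout.index(v)
        mat[i, j] = mat[j, i] = c
    network = CoherenceNetwork(layout=layout, coherence=mat, theta=0.2)
    return network, voronoi_adjacency(layout)


# Approximate top-view 2D positions (nose up, +y anterior) for the 19
# classic 10-20 electrodes.  Schematic unit-circle projection, adequate
# for Voronoi adjacency and rendering; not digitized head geometry.
_MONTAGE_10_20 = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.45, 0.52), "Fz": (0.0, 0.50),
    "F4": (0.45, 0.52), "F8": (0.81, 0.59),
    "T3": (-1.00, 0.00), "C3": (-0.50, 0.00), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.00), "T4": (1.00, 0.00),
    "T5": (-0.81, -0.59), "P3": (-0.45, -0.52), "Pz": (0.0, -0.50),
    "P4": (0.45, -0.52), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}


def montage_10_20() -> ElectrodeLayout:
    """Approximate 2D top-view layout for the 19 classic 10-20 labels."""
    labels = tuple(_MONTAGE_10_20)
    positions = np.array([_MONTAGE_10_20[lab] for lab in labels])
    return ElectrodeLayout(labels=labels, positions=positions)


def fixture(name: str):
    """Built-in fixtures by name.

    ``fig3-grid`` -> ElectrodeLayout; ``table1`` -> (CoherenceNetwork,
    SpatialAdjacency); ``montage-10-20`` -> ElectrodeLayout.
    """
    table = {
        "fig3-grid": fig3_grid_layout,
        "table1": table1_network,
        "montage-10-20": montage_10_20,
    }
    try:
        return table[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(table)}"
        ) from None


@dataclass(frozen=True)
class PlantedNetwork:
    """A coherence network with known (spatially contiguous) communities."""

    network: CoherenceNetwork
    adjacency: SpatialAdjacency
    truth: Partition
    params: dict

    def __post_init__(self) -> None:
        if not self.params["within"] > self.params["between"]:
            raise ValueError("within-community level must exceed between level")


def _grow_patches(
    rows: int, cols: int, n_communities: int, rng: np.random.Generator
) -> dict[tuple[int, int], int]:
    """Seeded multi-source BFS region growing: contiguous 4-connected
    patches covering the grid."""
    cells = [(r, k) for r in range(rows) for k in range(cols)]
    if n_communities > len(cells):
        raise ValueError(
            f"cannot grow {n_communities} communities on a {rows}x{cols} grid; "
            "use fewer communities"
        )
    seeds = [cells[i] for i in rng.choice(len(cells), n_communities, replace=False)]
    owner = {cell: i for i, cell in enumerate(seeds)}
    while len(owner) < len(cells):
        frontier = []
        for (r, k), i in sorted(owner.items()):
            for dr, dk in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nb = (r + dr, k + dk)
                if 0 <= nb[0] < rows and 0 <= nb[1] < cols and nb not in owner:
                    frontier.append((nb, i))
        pick = frontier[rng.integers(len(frontier))]
        owner[pick[0]] = pick[1]
    return owner


def planted_partition_network(
    rows: int = 3,
    cols: int = 4,
    n_communities: int = 2,
    within: float = 0.7,
    between: float = 0.1,
    jitter: float = 0.05,
    theta: float = 0.3,
    seed: int = 0,
) -> PlantedNetwork:
    """Grid coherence network with planted contiguous communities.

    Pairs inside a community get coherence ``within + jitter*U(-1,1)``,
    pairs across communities ``between + jitter*U(-1,1)``, clamped to
    [0, 1]; the matrix is symmetric with zero diagonal and reproducible
    per seed.  Defaults mirror the regime the detection methods assume:
    strong within-community coherence well above the threshold, weak
    between-community coherence below it.
    """
    if not within > between >= 0:
        raise ValueError("need within > between >= 0")
    rng = np.random.default_rng(seed)
    layout = grid_layout(rows, cols)
    owner = _grow_patches(rows, cols, n_communities, rng)
    comm = {
        layout.labels[r * cols + k]: i for (r, k), i in owner.items()
    }
    n = len(layout)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same = comm[layout.labels[i]] == comm[layout.labels[j]]
            base = within if same else between
            c = base + jitter * rng.uniform(-1.0, 1.0)
            mat[i, j] = mat[j, i] = float(np.clip(c, 0.0, 1.0))
    network = CoherenceNetwork(layout=layout, coherence=mat, theta=theta)
    truth = Partition.from_labels(comm)
    return PlantedNetwork(
        network=network,
        adjacency=voronoi_adjacency(layout),
        truth=truth,
        params={
            "within": within,
            "between": between,
            "jitter": jitter,
            "theta": theta,
            "seed": seed,
        },
    )


def simulate_recording(
    layout: ElectrodeLayout,
    truth: Partition,
    L: int = 13,
    T: int = 256,
    fs: float = 256.0,
    source_freq: float = 10.0,
    snr: float = 1.0,
    seed: int = 0,
    p: float = 0.01,
) -> SegmentedRecording:
    """Segmented multichannel recording with community-shared narrowband
    sources.

    Every community of ``truth`` shares one latent sinusoid at
    ``source_freq`` whose phase is redrawn per segment; channels see
    ``snr * source + unit white noise``.  Channels in different
    communities (and channels outside ``truth``) get independent
    sources, so between-community coherence follows the independence
    null.  ``snr = 0`` yields pure noise; large ``snr`` drives
    within-community coherence toward 1 at the source frequency.
    """
    if L < 2:
        raise ValueError("need L >= 2 segments")
    rng = np.random.default_rng(seed)
    t = np.arange(T) / fs
    comm_of = truth.to_assignment()
    next_id = max(comm_of.values(), default=0)
    for lab in layout.labels:
        if lab not in comm_of:  # uncovered channels: private sources
            next_id += 1
            comm_of[lab] = next_id

    sources: dict[int, np.ndarray] = {}
    for cid in sorted(set(comm_of.values())):
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(L, 1))
        sources[cid] = np.sqrt(2.0) * np.cos(
            2.0 * np.pi * source_freq * t[None, :] + phases
        )

    data = np.empty((len(layout), L, T))
    for i, lab in enumerate(layout.labels):
        noise = rng.standard_normal((L, T))
        data[i] = snr * sources[comm_of[lab]] + noise
    return SegmentedRecording(labels=layout.labels, data=data, fs=fs, p=p)
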