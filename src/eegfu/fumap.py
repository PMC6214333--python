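"""FU summary statistics and FU-map construction / rendering.

An FU map shows the electrode layout as clipped Voronoi cells, one gray
level per displayed functional unit (Voronoi-adjacent FUs always differ;
FUs below the display size are white), a circle at each displayed FU's
barycenter colored by its average coherence, and a line between
displayed FU pairs whose inter-FU coherence reaches the line threshold,
colored by that value.  Both summaries average over *all* electrode
pairs, including sub-threshold coherences:

    c_hat(C)      = sum_{v!=v' in C} c(v,v') / (|C| (|C|-1))
    c'(C1, C2)    = sum_{v in C1, v' in C2} c(v,v') / (|C1| |C2|)

Rendering is SVG-first (hand-written, byte-stable for fixed inputs) with
a matplotlib PNG fallback; circle and line colors come from one fixed
sequential colormap over the full [0, 1] domain so maps are comparable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import matplotlib
import numpy as np
from matplotlib import colors as mcolors
from matplotlib import pyplot as plt
from shapely.geometry import Point, Polygon

from .model import (
    CoherenceNetwork,
    ElectrodeLayout,
    Partition,
    SpatialAdjacency,
    voronoi_adjacency,
)

__all__ = [
    "FUSummary",
    "FUMapSpec",
    "average_coherence",
    "inter_fu_coherence",
    "summarize_fus",
    "build_fu_map",
    "render_fu_map",
]

#: fixed sequential colormap for circles and lines, domain [0, 1]
COLORMAP = "viridis"


def average_coherence(members, network: CoherenceNetwork) -> float | None:
    """Mean coherence over ordered member pairs; None for |C| < 2
    (rendered as an uncolored circle)."""
    members = sorted(set(members))
    k = len(members)
    if k < 2:
        return None
    idx = [network.layout.index(v) for v in members]
    sub = network.coherence[np.ix_(idx, idx)]
    return float(sub.sum() / (k * (k - 1)))


def inter_fu_coherence(C1, C2, network: CoherenceNetwork) -> float:
    """Mean coherence over cross pairs of two disjoint, non-empty FUs."""
    C1, C2 = set(C1), set(C2)
    if not C1 or not C2:
        raise ValueError("FUs must be non-empty")
    if C1 & C2:
        raise ValueError(f"FUs overlap: {sorted(C1 & C2)}")
    if sorted(C2) < sorted(C1):  # fixed summation order: exact symmetry
        C1, C2 = C2, C1
    i1 = [network.layout.index(v) for v in sorted(C1)]
    i2 = [network.layout.index(v) for v in sorted(C2)]
    return float(network.coherence[np.ix_(i1, i2)].sum() / (len(C1) * len(C2)))


@dataclass(frozen=True)
class FUSummary:
    """Per-FU and per-FU-pair summaries for one partition."""

    fus: tuple[tuple[str, ...], ...]
    sizes: tuple[int, ...]
    average: tuple[float | None, ...]
    barycenters: tuple[tuple[float, float], ...]
    total_strength: tuple[float, ...]
    inter: tuple[tuple[int, int, float], ...]  # (fu_i, fu_j, c') 1-based


def summarize_fus(
    partition: Partition, network: CoherenceNetwork
) -> FUSummary:
    from .mcb import total_strength  # reused for reporting
    from .model import significant_graph

    graph = significant_graph(network)
    fus = partition.communities
    bary = tuple(
        tuple(
            np.mean([network.layout.position_of(v) for v in fu], axis=0).round(9)
        )
        for fu in fus
    )
    inter = tuple(
        (i + 1, j + 1, inter_fu_coherence(fus[i], fus[j], network))
        for i in range(len(fus))
        for j in range(i + 1, len(fus))
    )
    return FUSummary(
        fus=fus,
        sizes=tuple(len(fu) for fu in fus),
        average=tuple(average_coherence(fu, network) for fu in fus),
        barycenters=bary,
        total_strength=tuple(total_strength(fu, graph) for fu in fus),
        inter=inter,
    )


# ---------------------------------------------------------------------------
# FU map construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FUMapSpec:
    """Render-ready FU map description.

    ``cells`` are clipped Voronoi polygons per electrode; ``cell_gray``
    holds one gray level in (0, 1] per electrode or None for white;
    ``circles`` are (x, y, value-or-None) per displayed FU; ``lines``
    are (fu_i, fu_j, x1, y1, x2, y2, value).
    """

    labels: tuple[str, ...]
    cells: tuple[tuple[tuple[float, float], ...], ...]
    fus: tuple[tuple[str, ...], ...]
    displayed: tuple[int, ...]  # 1-based ids of displayed FUs
    cell_gray: tuple[float | None, ...]
    circles: tuple[tuple[float, float, float | None], ...]
    lines: tuple[tuple[int, int, float, float, float, float, float], ...]
    colormap: str
    domain: tuple[float, float]

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def _gray_palette(i: int) -> float:
    """Deterministic sequence of distinct gray levels in [0.25, 0.95]
    (van der Corput bit-reversal, so nearby indices differ strongly)."""
    x, denom, k = 0.0, 0.5, i + 1
    while k:
        x += denom * (k & 1)
        k >>= 1
        denom /= 2.0
    return round(0.95 - 0.70 * x, 6)


def _clip_region(layout: ElectrodeLayout, clip: str) -> Polygon:
    pos = layout.positions
    span = float(np.ptp(pos, axis=0).max()) or 1.0
    if clip == "circle":
        center = pos.mean(axis=0)
        radius = 1.15 * float(np.linalg.norm(pos - center, axis=1).max())
        return Point(*center).buffer(radius, quad_segs=32)
    hull = Polygon(pos[_convex_hull_indices(pos)])
    return hull.buffer(0.15 * span, quad_segs=8)


def _convex_hull_indices(pos: np.ndarray) -> np.ndarray:
    from scipy.spatial import ConvexHull

    return ConvexHull(pos).vertices


def _voronoi_cells(
    layout: ElectrodeLayout, clip: str
) -> tuple[tuple[tuple[float, float], ...], ...]:
    """Voronoi cell of every electrode, clipped to the render region by
    iterated half-plane intersection (robust for unbounded cells)."""
    pos = layout.positions
    region = _clip_region(layout, clip)
    span = float(np.ptp(pos, axis=0).max()) or 1.0
    far = 10.0 * span + 10.0
    cells = []
    for i in range(len(pos)):
        cell = region
        for j in range(len(pos)):
            if j == i:
                continue
            d = pos[j] - pos[i]
            d = d / np.linalg.norm(d)
            perp = np.array([-d[1], d[0]])
            mid = (pos[i] + pos[j]) / 2.0
            # rectangle on electrode i's side of the bisector
            half = Polygon(
                [
                    mid + far * perp,
                    mid - far * perp,
                    mid - far * perp - 2.0 * far * d,
                    mid + far * perp - 2.0 * far * d,
                ]
            )
            cell = cell.intersection(half)
        coords = tuple(
            (round(float(x), 6), round(float(y), 6))
            for x, y in cell.exterior.coords[:-1]
        )
        cells.append(coords)
    return tuple(cells)


def build_fu_map(
    partition: Partition,
    network: CoherenceNetwork,
    display_min_size: int = 5,
    line_threshold: float | None = None,
    *,
    strict_lines: bool = False,
    clip: str = "hull",
    adjacency: SpatialAdjacency | None = None,
) -> FUMapSpec:
    """Construct the render-ready FU map for a partition.

    FUs with fewer than ``display_min_size`` members render white; the
    line threshold defaults to the network's significance threshold
    ``theta`` and uses a closed comparison unless ``strict_lines``.
    Gray levels are greedily assigned over an ordered palette so that
    Voronoi-adjacent displayed FUs never share a level.
    """
    layout = network.layout
    if not partition.members() <= set(layout.labels):
        extra = sorted(partition.members() - set(layout.labels))
        raise ValueError(f"partition labels not in layout: {extra}")
    if line_threshold is None:
        line_threshold = network.theta
    if adjacency is None:
        adjacency = (
            voronoi_adjacency(layout) if len(layout) >= 2 else
            SpatialAdjacency(layout.labels, frozenset())
        )

    fus = partition.communities
    displayed = [
        i for i, fu in enumerate(fus) if len(fu) >= display_min_size
    ]

    # FU adjacency: any Voronoi-adjacent electrode pair across two FUs
    fu_of = {v: i for i, fu in enumerate(fus) for v in fu}
    fu_adj: set[tuple[int, int]] = set()
    for v in layout.labels:
        for u in adjacency.neighbors(v):
            iv, iu = fu_of.get(v), fu_of.get(u)
            if iv is not None and iu is not None and iv != iu:
                fu_adj.add((min(iv, iu), max(iv, iu)))

    # greedy coloring: largest displayed FUs first, palette order fixed
    gray_of: dict[int, float] = {}
    for i in sorted(displayed, key=lambda i: (-len(fus[i]), fus[i][0])):
        taken = {
            gray_of[j]
            for j in gray_of
            if (min(i, j), max(i, j)) in fu_adj
        }
        k = 0
        while _gray_palette(k) in taken:
            k += 1
        gray_of[i] = _gray_palette(k)

    cell_gray = tuple(
        gray_of.get(fu_of[v]) if v in fu_of else None for v in layout.labels
    )

    bary = {
        i: tuple(
            np.mean([layout.position_of(v) for v in fus[i]], axis=0)
        )
        for i in displayed
    }
    circles = tuple(
        (
            round(float(bary[i][0]), 6),
            round(float(bary[i][1]), 6),
            average_coherence(fus[i], network),
        )
        for i in displayed
    )

    lines = []
    for a in range(len(displayed)):
        for b in range(a + 1, len(displayed)):
            i, j = displayed[a], displayed[b]
            c = inter_fu_coherence(fus[i], fus[j], network)
            keep = c > line_threshold if strict_lines else c >= line_threshold
            if keep:
                lines.append(
                    (
                        i + 1,
                        j + 1,
                        round(float(bary[i][0]), 6),
                        round(float(bary[i][1]), 6),
                        round(float(bary[j][0]), 6),
                        round(float(bary[j][1]), 6),
                        c,
                    )
                )

    return FUMapSpec(
        labels=layout.labels,
        cells=_voronoi_cells(layout, clip),
        fus=fus,
        displayed=tuple(i + 1 for i in displayed),
        cell_gray=cell_gray,
        circles=circles,
        lines=tuple(lines),
        colormap=COLORMAP,
        domain=(0.0, 1.0),
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _color_hex(value: float, cmap_name: str) -> str:
    cmap = matplotlib.colormaps[cmap_name]
    return mcolors.to_hex(cmap(float(np.clip(value, 0.0, 1.0))))


def _svg(spec: FUMapSpec) -> str:
    pts = [p for cell in spec.cells for p in cell]
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    xmin, xmax, ymin, ymax = min(xs), max(xs), min(ys), max(ys)
    span = max(xmax - xmin, ymax - ymin) or 1.0
    size = 560.0
    margin = 20.0
    bar_w = 90.0
    scale = size / span

    def tx(x: float) -> float:
        return round(margin + (x - xmin) * scale, 2)

    def ty(y: float) -> float:
        # y flip: +y (anterior, nose) points up
        return round(margin + (ymax - y) * scale, 2)

    W = margin * 2 + (xmax - xmin) * scale + bar_w
    H = margin * 2 + (ymax - ymin) * scale
    out = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{W:.0f}" '
        f'height="{H:.0f}" viewBox="0 0 {W:.0f} {H:.0f}">',
        '<rect width="100%" height="100%" fill="white"/>',
    ]
    for cell, gray in zip(spec.cells, spec.cell_gray):
        fill = (
            "#ffffff"
            if gray is None
            else mcolors.to_hex((gray, gray, gray))
        )
        points = " ".join(f"{tx(x)},{ty(y)}" for x, y in cell)
        out.append(
            f'<polygon points="{points}" fill="{fill}" '
            'stroke="black" stroke-width="1"/>'
        )
    for i, j, x1, y1, x2, y2, c in spec.lines:
        out.append(
            f'<line x1="{tx(x1)}" y1="{ty(y1)}" x2="{tx(x2)}" y2="{ty(y2)}" '
            f'stroke="{_color_hex(c, spec.colormap)}" stroke-width="4"/>'
        )
    r = round(0.035 * size, 2)
    for x, y, val in spec.circles:
        fill = "none" if val is None else _color_hex(val, spec.colormap)
        out.append(
            f'<circle cx="{tx(x)}" cy="{ty(y)}" r="{r}" fill="{fill}" '
            'stroke="black" stroke-width="1.5"/>'
        )
    # color bar (rects named distinctly from cells' polygons)
    n_steps = 32
    bx = margin + (xmax - xmin) * scale + 30.0
    bh = (H - 2 * margin) / n_steps
    for k in range(n_steps):
        v = (k + 0.5) / n_steps
        y = H - margin - (k + 1) * bh
        out.append(
            f'<rect x="{bx:.2f}" y="{y:.2f}" width="18" height="{bh:.2f}" '
            f'fill="{_color_hex(v, spec.colormap)}"/>'
        )
    for frac, text in ((0.0, "0.0"), (0.5, "0.5"), (1.0, "1.0")):
        y = H - margin - frac * (H - 2 * margin)
        out.append(
            f'<text x="{bx + 24:.2f}" y="{y + 4:.2f}" font-size="12" '
            f'font-family="sans-serif">{text}</text>'
        )
    out.append("</svg>")
    return "\n".join(out) + "\n"


def _render_png(spec: FUMapSpec, path) -> None:
    fig, ax = plt.subplots(figsize=(6.4, 5.6))
    cmap = matplotlib.colormaps[spec.colormap]
    for cell, gray in zip(spec.cells, spec.cell_gray):
        xy = np.array(cell)
        face = "white" if gray is None else (gray, gray, gray)
        ax.fill(xy[:, 0], xy[:, 1], facecolor=face, edgecolor="black", lw=0.8)
    for i, j, x1, y1, x2, y2, c in spec.lines:
        ax.plot([x1, x2], [y1, y2], color=cmap(c), lw=3, zorder=3)
    for x, y, val in spec.circles:
        face = "none" if val is None else cmap(val)
        ax.scatter([x], [y], s=180, facecolor=face, edgecolor="black", zorder=4)
    sm = plt.cm.ScalarMappable(
        cmap=cmap, norm=mcolors.Normalize(*spec.domain)
    )
    fig.colorbar(sm, ax=ax, label="coherence")
    ax.set_aspect("equal")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def render_fu_map(spec: FUMapSpec, path, format: str | None = None) -> None:
    """Write the FU map to ``path`` as SVG (canonical, byte-stable) or PNG.

    The format is inferred from the path suffix when not given.
    """
    fmt = (format or str(path).rsplit(".", 1)[-1]).lower()
    if fmt == "svg":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(_svg(spec))
    elif fmt == "png":
        _render_png(spec, path)
    else:
        raise ValueError(f"unsupported format {fmt!r} (svg or png)")
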