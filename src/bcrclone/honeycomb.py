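"""Deterministic hexagonal (honeycomb) layout of clonal families.

Families are ranked by descending size and packed center-to-periphery as
contiguous blobs of hexes grown along the axial spiral, with one hex of
padding between neighbouring families. Each occupied hex is one cell,
colour-keyed by isotype at render time. Axial (q, r) coordinates, pointy-top
orientation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import pandas as pd

from .clonal_inference import ClonalFamily
from .isotypes import NO_ISOTYPE, ISOTYPE_ORDER

# axial neighbour directions, pointy-top
DIRECTIONS = ((1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1))

Coord = tuple[int, int]


def hex_distance(a: Coord, b: Coord = (0, 0)) -> int:
    """Hex grid distance between two axial coordinates."""
    dq, dr = a[0] - b[0], a[1] - b[1]
    return (abs(dq) + abs(dr) + abs(dq + dr)) // 2


def neighbors(c: Coord) -> list[Coord]:
    return [(c[0] + dq, c[1] + dr) for dq, dr in DIRECTIONS]


def hex_spiral(n: int) -> list[Coord]:
    """First *n* coordinates of the axial spiral: origin, ring 1 (6 hexes),
    ring 2 (12 hexes), ... Consecutive coordinates within a ring are adjacent."""
    if n < 0:
        raise ValueError("n must be >= 0")
    out: list[Coord] = []
    if n == 0:
        return out
    out.append((0, 0))
    k = 1
    while len(out) < n:
        q, r = -k, k  # k steps in direction (-1, 1) from the origin
        for dq, dr in DIRECTIONS:
            for _ in range(k):
                if len(out) >= n:
                    return out
                out.append((q, r))
                q, r = q + dq, r + dr
        k += 1
    return out


@dataclasses.dataclass
class HexLayout:
    """Per-cell hex coordinates plus family placement ranks."""

    table: pd.DataFrame  # columns: cell_id, clone_id, q, r, isotype
    family_rank: dict[str, int]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _isotype_sort_key(iso: str) -> tuple[int, str]:
    try:
        return (ISOTYPE_ORDER.index(iso), iso)
    except ValueError:
        return (len(ISOTYPE_ORDER), iso)


class _Spiral:
    """Lazily extended spiral with coordinate -> index lookup."""

    def __init__(self) -> None:
        self.coords: list[Coord] = []
        self.index: dict[Coord, int] = {}
        self._grow(64)

    def _grow(self, upto: int) -> None:
        if upto <= len(self.coords):
            return
        self.coords = hex_spiral(upto)
        self.index = {c: i for i, c in enumerate(self.coords)}

    def index_of(self, c: Coord) -> int:
        while c not in self.index:
            self._grow(len(self.coords) * 2)
        return self.index[c]

    def first_free(self, used: set[Coord]) -> Coord:
        i = 0
        while True:
            while i >= len(self.coords):
                self._grow(len(self.coords) * 2)
            if self.coords[i] not in used:
                return self.coords[i]
            i += 1


def layout_families(families: Sequence[ClonalFamily]) -> HexLayout:
    """Pack families center-to-periphery in descending size order.

    Each family occupies a contiguous blob grown greedily towards the lowest
    free spiral index; after placement, the blob's border hexes are blocked
    so distinct families never touch. Within a family, cells are laid out in
    isotype locus order, then by barcode.
    """
    if not families:
        raise ValueError("at least one family required")
    spiral = _Spiral()
    occupied: set[Coord] = set()
    blocked: set[Coord] = set()
    rows = []
    ranks: dict[str, int] = {}
    ordered = sorted(families, key=lambda f: (-f.size, f.clone_id))
    for rank, fam in enumerate(ordered, start=1):
        ranks[fam.clone_id] = rank
        unavailable = occupied | blocked
        seed = spiral.first_free(unavailable)
        blob = [seed]
        blob_set = {seed}
        while len(blob) < fam.size:
            candidates = {
                nb
                for hex_ in blob
                for nb in neighbors(hex_)
                if nb not in unavailable and nb not in blob_set
            }
            nxt = min(candidates, key=spiral.index_of)
            blob.append(nxt)
            blob_set.add(nxt)
        blob.sort(key=spiral.index_of)
        occupied |= blob_set
        blocked |= {nb for hex_ in blob for nb in neighbors(hex_)} - occupied
        cells = sorted(
            fam.members, key=lambda c: (_isotype_sort_key(c.heavy.isotype), c.cell_id)
        )
        for cell, (q, r) in zip(cells, blob):
            rows.append({
                "cell_id": cell.cell_id, "clone_id": fam.clone_id,
                "q": q, "r": r, "isotype": cell.heavy.isotype,
            })
    table = pd.DataFrame(rows, columns=["cell_id", "clone_id", "q", "r", "isotype"])
    return HexLayout(table=table, family_rank=ranks)


# ---------------------------------------------------------------------------
# rendering

_COLORS = {
    "IGHM": "#1f77b4", "IGHD": "#17becf", "IGHG3": "#9467bd", "IGHG1": "#d62728",
    "IGHA1": "#2ca02c", "IGHG2": "#ff7f0e", "IGHG4": "#e377c2", "IGHE": "#bcbd22",
    "IGHA2": "#8c564b", NO_ISOTYPE: "#bbbbbb",
}


def axial_to_cartesian(q: int, r: int, size: float = 1.0) -> tuple[float, float]:
    """Pointy-top axial -> Cartesian conversion for rendering."""
    x = size * (3 ** 0.5) * (q + r / 2.0)
    y = size * 1.5 * r
    return x, y


def render_svg(layout: HexLayout, path, size: float = 1.0) -> None:
    """Draw the honeycomb as SVG: one pointy-top hexagon per cell, coloured by
    isotype ('x' marks cells with undetermined isotype)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import RegularPolygon

    fig, ax = plt.subplots(figsize=(8, 8))
    for row in layout.table.itertuples(index=False):
        x, y = axial_to_cartesian(row.q, row.r, size)
        color = _COLORS.get(row.isotype, "#bbbbbb")
        ax.add_patch(RegularPolygon(
            (x, y), numVertices=6, radius=size * 0.95,
            orientation=0.0, facecolor=color, edgecolor="white", linewidth=0.3,
        ))
        if row.isotype == NO_ISOTYPE:
            ax.text(x, y, "x", ha="center", va="center", fontsize=4)
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
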