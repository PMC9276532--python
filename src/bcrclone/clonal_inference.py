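"""Clonal family inference.

Cells are first grouped by heavy-chain V gene, J gene and junction length;
within each group, single-linkage hierarchical clustering on the
length-normalized junction Hamming distance, cut at a threshold, defines
heavy-chain clones. The threshold is either estimated from the bimodal
distance-to-nearest-neighbour distribution (valley between the clonally
related and unrelated modes) or fixed at the conventional 0.15 operating
value. Heavy clones are then corrected with the light-chain partners: cells
of one heavy clone that do not share any light-chain group (locus, V gene,
J gene, junction length) are split into separate families.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter, defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import gaussian_kde
from sklearn.metrics import adjusted_rand_score

from .io_airr import ChainRecord, PairedCell
from .isotypes import NO_ISOTYPE
from .lineage import mutation_frequency

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.15

PartitionKey = tuple[str, str, int]


@dataclasses.dataclass
class ClonePartition:
    """Assignment of every cell to exactly one clone."""

    assignments: dict[str, str]
    threshold_used: float
    partition_keys: dict[str, PartitionKey]

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = defaultdict(list)
        for cell_id, clone in self.assignments.items():
            out[clone].append(cell_id)
        return {k: sorted(v) for k, v in out.items()}


@dataclasses.dataclass
class ClonalFamily:
    """An inferred clonal family with per-sample membership and isotype usage."""

    clone_id: str
    members: list[PairedCell]
    partition_key: PartitionKey
    sample_counts: dict[str, int]
    isotype_counts: dict[str, int]
    mean_vh_mutation: float | None
    representative_heavy: ChainRecord
    representative_light: ChainRecord

    @property
    def size(self) -> int:
        return len(self.members)


def partition_key(cell: PairedCell) -> PartitionKey:
    h = cell.heavy
    return (h.v_gene, h.j_gene, len(h.junction))


def light_groups(cell: PairedCell) -> frozenset[tuple[str, str, str, int]]:
    """Light-chain compatibility groups of a cell: (locus, V gene, J gene, junction length)."""
    return frozenset(
        (lc.locus, lc.v_gene, lc.j_gene, len(lc.junction)) for lc in cell.lights
    )


# ---------------------------------------------------------------------------
# distances

def junction_distance(a: str, b: str) -> float:
    """Length-normalized Hamming distance between two equal-length junctions.

    Positions where either sequence has N are excluded from both numerator
    and denominator.
    """
    if len(a) != len(b) or len(a) == 0:
        raise ValueError(f"junction lengths differ or are zero: {len(a)} vs {len(b)}")
    num = den = 0
    for x, y in zip(a, b):
        if x == "N" or y == "N":
            continue
        den += 1
        if x != y:
            num += 1
    return num / den if den else 0.0


def _pairwise_matrix(junctions: Sequence[str]) -> np.ndarray:
    """Dense matrix of junction distances for same-length sequences."""
    arr = np.frombuffer("".join(junctions).encode(), dtype="S1").reshape(len(junctions), -1)
    valid = arr != b"N"
    n = len(junctions)
    dist = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid
        mism = (arr[i] != arr) & both
        den = both.sum(axis=1)
        dist[i] = np.where(den > 0, mism.sum(axis=1) / np.maximum(den, 1), 0.0)
    np.fill_diagonal(dist, 0.0)
    return dist


def nearest_neighbor_distances(cells: Sequence[PairedCell]) -> dict[str, float | None]:
    """Per-cell minimum junction distance to any other heavy chain in its
    (V gene, J gene, junction length) group; None for singleton groups."""
    if not cells:
        raise ValueError("at least one cell required")
    groups: dict[PartitionKey, list[PairedCell]] = defaultdict(list)
    for cell in cells:
        groups[partition_key(cell)].append(cell)
    out: dict[str, float | None] = {}
    for members in groups.values():
        if len(members) == 1:
            out[members[0].cell_id] = None
            continue
        dist = _pairwise_matrix([c.heavy.junction for c in members])
        np.fill_diagonal(dist, np.inf)
        mins = dist.min(axis=1)
        for cell, d in zip(members, mins):
            out[cell.cell_id] = float(d)
    return out


# ---------------------------------------------------------------------------
# threshold estimation

def estimate_threshold(
    distances: Mapping[str, float | None] | Iterable[float | None],
    default: float = DEFAULT_THRESHOLD,
    valley_window: tuple[float, float] = (0.02, 0.45),
    grid_step: float = 0.001,
) -> float:
    """Valley of the distance-to-nearest density between its two main modes.

    A Gaussian kernel density (Silverman bandwidth) is evaluated on a fine
    grid; the location of the minimum density between the two highest local
    maxima is returned if it falls inside *valley_window*, otherwise the
    *default* operating value (logged). Degenerate inputs (empty, constant,
    unimodal) fall back to the default as well.
    """
    if isinstance(distances, Mapping):
        distances = list(distances.values())
    vals = np.array([d for d in distances if d is not None], dtype=float)
    if vals.size < 5 or np.std(vals) == 0:
        log.info("threshold fallback %.3f (too few or constant distances)", default)
        return default
    kde = gaussian_kde(vals, bw_method="silverman")
    hi = min(1.0, float(vals.max()) + 0.1)
    grid = np.arange(0.0, hi + grid_step, grid_step)
    dens = kde(grid)
    padded = np.concatenate(([-np.inf], dens, [-np.inf]))
    peaks = [
        i for i in range(len(dens))
        if padded[i + 1] > padded[i] and padded[i + 1] >= padded[i + 2]
    ]
    if len(peaks) < 2:
        log.info("threshold fallback %.3f (unimodal density)", default)
        return default
    top = sorted(peaks, key=lambda i: dens[i], reverse=True)[:2]
    lo_i, hi_i = sorted(top)
    valley_i = lo_i + int(np.argmin(dens[lo_i:hi_i + 1]))
    valley = float(grid[valley_i])
    if valley_window[0] < valley < valley_window[1]:
        return valley
    log.info("threshold fallback %.3f (valley %.3f outside window)", default, valley)
    return default


# ---------------------------------------------------------------------------
# clustering

def _assign_ids(groups: list[tuple[PartitionKey, list[PairedCell]]],
                threshold: float) -> ClonePartition:
    """Deterministic clone ids: groups sorted by (partition key, smallest barcode)."""
    ordered = sorted(groups, key=lambda kg: (kg[0], min(c.cell_id for c in kg[1])))
    assignments: dict[str, str] = {}
    keys: dict[str, PartitionKey] = {}
    for idx, (key, members) in enumerate(ordered, start=1):
        clone_id = f"{idx:06d}"
        keys[clone_id] = key
        for cell in members:
            assignments[cell.cell_id] = clone_id
    return ClonePartition(assignments=assignments, threshold_used=threshold,
                          partition_keys=keys)


def cluster_clones(cells: Sequence[PairedCell], threshold: float) -> ClonePartition:
    """Single-linkage clustering of heavy junctions within V/J/length groups,
    cut at junction distance <= *threshold*."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    by_key: dict[PartitionKey, list[PairedCell]] = defaultdict(list)
    for cell in cells:
        by_key[partition_key(cell)].append(cell)

    clusters: list[tuple[PartitionKey, list[PairedCell]]] = []
    for key, members in by_key.items():
        members = sorted(members, key=lambda c: c.cell_id)
        if len(members) == 1:
            clusters.append((key, members))
            continue
        dist = _pairwise_matrix([c.heavy.junction for c in members])
        z = linkage(squareform(dist, checks=False), method="single")
        labels = fcluster(z, t=threshold, criterion="distance")
        by_label: dict[int, list[PairedCell]] = defaultdict(list)
        for cell, lab in zip(members, labels):
            by_label[lab].append(cell)
        for lab in sorted(by_label):
            clusters.append((key, by_label[lab]))
    return _assign_ids(clusters, threshold)


def refine_by_light_chain(p: ClonePartition, cells: Sequence[PairedCell]) -> ClonePartition:
    """Split heavy clones whose members are incompatible by light chain.

    Within each heavy clone, two cells are linked iff they share at least one
    light-chain group; connected components of that graph become the refined
    clones. The operation only ever splits clones and is idempotent.
    """
    by_id = {c.cell_id: c for c in cells}
    clusters: list[tuple[PartitionKey, list[PairedCell]]] = []
    for clone_id, member_ids in p.groups().items():
        key = p.partition_keys[clone_id]
        members = [by_id[i] for i in member_ids]
        # union-find over cells, joined through shared light groups
        parent = {c.cell_id: c.cell_id for c in members}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        group_owner: dict[tuple[str, str, str, int], str] = {}
        for cell in members:
            for g in sorted(light_groups(cell)):
                if g in group_owner:
                    ra, rb = find(group_owner[g]), find(cell.cell_id)
                    if ra != rb:
                        parent[rb] = ra
                else:
                    group_owner[g] = cell.cell_id
        comps: dict[str, list[PairedCell]] = defaultdict(list)
        for cell in members:
            comps[find(cell.cell_id)].append(cell)
        for root in sorted(comps):
            clusters.append((key, comps[root]))
    return _assign_ids(clusters, p.threshold_used)


# ---------------------------------------------------------------------------
# family construction

def _representative_heavy(members: Sequence[PairedCell]) -> tuple[ChainRecord, PairedCell]:
    counts = Counter(c.heavy.junction for c in members)
    best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    cell = min((c for c in members if c.heavy.junction == best), key=lambda c: c.cell_id)
    return cell.heavy, cell


def build_families(p: ClonePartition, cells: Sequence[PairedCell]) -> list[ClonalFamily]:
    """Materialize one :class:`ClonalFamily` per clone, largest first.

    Mean VH mutation load is computed against the N-masked germline alignment
    when present (the N mask over the junction excludes it automatically).
    """
    by_id = {c.cell_id: c for c in cells}
    missing = set(p.assignments) - set(by_id)
    if missing:
        raise ValueError(f"partition covers unknown cells: {sorted(missing)[:3]}...")
    families: list[ClonalFamily] = []
    for clone_id, member_ids in p.groups().items():
        members = [by_id[i] for i in member_ids]
        sample_counts = Counter(c.sample_id for c in members)
        isotype_counts = Counter(
            c.heavy.isotype for c in members if c.heavy.isotype != NO_ISOTYPE
        )
        muts = [
            mutation_frequency(c.heavy.sequence_alignment, c.heavy.germline_alignment)
            for c in members
            if c.heavy.sequence_alignment and c.heavy.germline_alignment
        ]
        rep_heavy, rep_cell = _representative_heavy(members)
        families.append(
            ClonalFamily(
                clone_id=clone_id,
                members=members,
                partition_key=p.partition_keys[clone_id],
                sample_counts=dict(sample_counts),
                isotype_counts=dict(isotype_counts),
                mean_vh_mutation=float(np.mean(muts)) if muts else None,
                representative_heavy=rep_heavy,
                representative_light=rep_cell.light,
            )
        )
    families.sort(key=lambda f: (-f.size, f.clone_id))
    return families


# ---------------------------------------------------------------------------
# partition comparison

def adjusted_rand_index(a: Mapping[str, object], b: Mapping[str, object]) -> float:
    """Chance-corrected agreement between two partitions of the same cells."""
    if set(a) != set(b):
        raise ValueError("partitions are over different cell universes")
    order = sorted(a)
    la = [a[k] for k in order]
    lb = [b[k] for k in order]
    return float(adjusted_rand_score(la, lb))
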