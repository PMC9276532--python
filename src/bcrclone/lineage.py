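"""Germline-rooted genealogical trees of clonal families.

Cells with identical V-region sequences are collapsed into variants; a
minimum-spanning-arborescence parsimony heuristic connects the variants to
the reconstructed germline; edges carry nucleotide and amino-acid mutation
counts. Edge labels are the Hamming distance between the edge's endpoint
sequences (observed parents, not inferred intermediates) — the convention is
recorded in the exports.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Sequence

import networkx as nx
from Bio.Data.CodonTable import unambiguous_dna_by_id

_CODON = dict(unambiguous_dna_by_id[1].forward_table)
for _stop in unambiguous_dna_by_id[1].stop_codons:
    _CODON[_stop] = "*"

_SKIP = frozenset("N.-")

GERMLINE = "germline"


def _valid(ch: str) -> bool:
    return ch not in _SKIP


def hamming(a: str, b: str) -> int:
    """Mismatch count over positions where neither sequence has N or a gap."""
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    return sum(1 for x, y in zip(a, b) if x != y and _valid(x) and _valid(y))


def mutation_frequency(
    seq: str,
    germ: str,
    junction_interval: tuple[int, int] | None = None,
) -> float:
    """Percent mutated positions of *seq* relative to *germ*.

    Positions with N or a gap in either sequence are excluded; so is the
    0-based half-open *junction_interval* when given (an N-masked junction in
    the germline is excluded automatically either way).
    """
    if len(seq) != len(germ):
        raise ValueError(f"aligned lengths differ: {len(seq)} vs {len(germ)}")
    mism = comp = 0
    for i, (x, y) in enumerate(zip(seq, germ)):
        if junction_interval and junction_interval[0] <= i < junction_interval[1]:
            continue
        if not (_valid(x) and _valid(y)):
            continue
        comp += 1
        if x != y:
            mism += 1
    return 100.0 * mism / comp if comp else 0.0


def aa_mutations(a: str, b: str) -> int:
    """Amino-acid differences between two aligned nt sequences, frame 0.

    Codons containing N or a gap in either sequence are skipped.
    """
    if len(a) != len(b):
        raise ValueError("aligned lengths differ")
    count = 0
    for i in range(0, len(a) - 2, 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if any(not _valid(ch) for ch in ca + cb):
            continue
        if _CODON.get(ca, "X") != _CODON.get(cb, "X"):
            count += 1
    return count


@dataclasses.dataclass
class Variant:
    """A distinct V-region sequence and the cells that carry it."""

    sequence: str
    cell_ids: tuple[str, ...]
    isotypes: tuple[str, ...]
    timepoints: tuple[object, ...]
    compartments: tuple[str, ...]

    @property
    def multiplicity(self) -> int:
        return len(self.cell_ids)


def collapse_identical(family, paired: bool = False) -> list[Variant]:
    """One Variant per distinct sequence; heavy V-region by default, heavy+light
    concatenation when *paired* (cells identical in VH but not VL stay apart)."""
    if not family.members:
        raise ValueError("empty family")
    groups: dict[str, list] = {}
    for cell in family.members:
        if cell.heavy.sequence_alignment is None:
            raise ValueError(f"cell {cell.cell_id} lacks sequence_alignment")
        key = cell.heavy.sequence_alignment
        if paired:
            if cell.light.sequence_alignment is None:
                raise ValueError(f"cell {cell.cell_id} light chain lacks sequence_alignment")
            key = key + cell.light.sequence_alignment
        groups.setdefault(key, []).append(cell)
    variants = []
    for seq in sorted(groups):
        cells = sorted(groups[seq], key=lambda c: c.cell_id)
        variants.append(
            Variant(
                sequence=seq,
                cell_ids=tuple(c.cell_id for c in cells),
                isotypes=tuple(c.heavy.isotype for c in cells),
                timepoints=tuple(c.timepoint for c in cells),
                compartments=tuple(c.compartment for c in cells),
            )
        )
    return variants


@dataclasses.dataclass
class LineageTree:
    """Germline-rooted tree over variants; edges labelled with mutation counts."""

    graph: nx.DiGraph
    root: str = GERMLINE

    @property
    def parsimony_score(self) -> int:
        return sum(d["nt_mutations"] for _, _, d in self.graph.edges(data=True))

    def variant(self, node: str) -> Variant | None:
        return self.graph.nodes[node].get("variant")

    def to_newick(self) -> str:
        """Newick string; branch lengths are nt mutation counts, node comments
        carry multiplicity / isotypes / timepoints."""

        def comment(node: str) -> str:
            v = self.variant(node)
            if v is None:
                return ""
            iso = "|".join(v.isotypes)
            tps = "|".join(str(t) for t in v.timepoints)
            return f"[&mult={v.multiplicity},iso={iso},tp={tps}]"

        def render(node: str) -> str:
            children = sorted(self.graph.successors(node))
            label = node + comment(node)
            if not children:
                return label
            inner = ",".join(
                render(ch) + f":{self.graph.edges[node, ch]['nt_mutations']}"
                for ch in children
            )
            return f"({inner}){label}"

        return render(self.root) + ";"

    def to_dot(self) -> str:
        """GraphViz DOT export; edge labels 'nt (aa)'."""
        lines = ["digraph lineage {", '  node [shape=circle];']
        for node in sorted(self.graph.nodes):
            v = self.variant(node)
            label = GERMLINE if v is None else f"{node}\\nn={v.multiplicity}"
            lines.append(f'  "{node}" [label="{label}"];')
        for a, b, d in sorted(self.graph.edges(data=True)):
            lines.append(f'  "{a}" -> "{b}" [label="{d["nt_mutations"]} ({d["aa_mutations"]})"];')
        lines.append("}")
        return "\n".join(lines)


def _mutated_positions(seq: str, germ: str) -> frozenset[int]:
    return frozenset(
        i for i, (x, y) in enumerate(zip(seq, germ))
        if x != y and _valid(x) and _valid(y)
    )


def build_tree(variants: Sequence[Variant], germline: str) -> LineageTree:
    """Parsimony heuristic: minimum spanning tree over {germline} + variants
    with Hamming weights, oriented away from the germline, then zero-gain
    splices that place a variant whose mutations are a subset of another's
    on the path to it. Ties break on lexicographic sequence order.
    """
    if not variants:
        raise ValueError("at least one variant required")
    for v in variants:
        if len(v.sequence) != len(germline):
            raise ValueError("variant and germline aligned lengths differ")
    ordered = sorted(variants, key=lambda v: v.sequence)
    labels = [GERMLINE] + [f"v{i}" for i in range(len(ordered))]
    seqs = {GERMLINE: germline}
    seqs.update({f"v{i}": v.sequence for i, v in enumerate(ordered)})
    n = len(labels)
    dist = {
        (labels[i], labels[j]): hamming(seqs[labels[i]], seqs[labels[j]])
        for i in range(n) for j in range(n)
    }

    # Prim's MST from the germline with deterministic tie-breaks on node order.
    rank = {lab: i for i, lab in enumerate(labels)}
    in_tree = {GERMLINE}
    best: dict[str, tuple[int, str]] = {
        lab: (dist[GERMLINE, lab], GERMLINE) for lab in labels[1:]
    }
    parent: dict[str, str] = {}
    while len(in_tree) < n:
        nxt = min(
            (lab for lab in labels if lab not in in_tree),
            key=lambda lab: (best[lab][0], rank[best[lab][1]], rank[lab]),
        )
        parent[nxt] = best[nxt][1]
        in_tree.add(nxt)
        for lab in labels[1:]:
            if lab in in_tree:
                continue
            cand = dist[nxt, lab]
            if (cand, rank[nxt]) < (best[lab][0], rank[best[lab][1]]):
                best[lab] = (cand, nxt)

    muts = {lab: _mutated_positions(seqs[lab], germline) for lab in labels}

    # zero-gain splice: move v under an ancestral sibling on the same path
    changed = True
    passes = 0
    while changed and passes < n:
        changed = False
        passes += 1
        for v in labels[1:]:
            p = parent[v]
            siblings = sorted(
                (s for s in labels[1:] if s != v and parent.get(s) == p),
                key=lambda s: rank[s],
            )
            for s in siblings:
                if (
                    muts[s] < muts[v]
                    and dist[p, s] + dist[s, v] == dist[p, v]
                ):
                    parent[v] = s
                    changed = True
                    break

    g = nx.DiGraph()
    g.add_node(GERMLINE, sequence=germline)
    for i, v in enumerate(ordered):
        g.add_node(f"v{i}", variant=v, sequence=v.sequence)
    for child, par in parent.items():
        g.add_edge(
            par, child,
            nt_mutations=dist[par, child],
            aa_mutations=aa_mutations(seqs[par], seqs[child]),
        )
    return LineageTree(graph=g)


def annotate_isotype_branches(tree: LineageTree) -> LineageTree:
    """Attach per-node isotype multisets and a multi-isotype flag, in place.

    Cells without a determined isotype do not count towards distinctness.
    """
    from .isotypes import NO_ISOTYPE

    for node in tree.graph.nodes:
        v = tree.variant(node)
        if v is None:
            continue
        counts = Counter(v.isotypes)
        distinct = {iso for iso in counts if iso != NO_ISOTYPE}
        tree.graph.nodes[node]["isotype_counts"] = dict(counts)
        tree.graph.nodes[node]["multi_isotype"] = len(distinct) > 1
    return tree
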