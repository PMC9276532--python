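"""Synthetic paired-chain repertoire simulator with ground truth.

Emulates multi-timepoint, multi-compartment single-cell BCR data with known
clonal structure: power-law family sizes, per-family VDJ ancestors over a
random germline reference, binary lineage growth with Poisson somatic
hypermutation per edge, ordered (irreversible) isotype switching,
memory/plasmablast compartments and multi-year persistence. Every cell's
true family, lineage position, switch history and sampling metadata are
recorded so each downstream analysis stage can be checked against truth.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .io_airr import ChainRecord, GermlineReference, PairedCell
from .isotypes import NO_ISOTYPE, downstream_classes

NT = np.array(list("ACGT"))


@dataclasses.dataclass
class SimConfig:
    """Study conditions for one simulated repertoire.

    Defaults emulate a scaled-down memory B-cell dataset from one donor:
    Zipf-distributed family sizes, human-like junction length ranges, a mean
    of one point mutation per lineage edge, moderate class switching, a
    60:40 kappa:lambda ratio, two sampling years with most families
    persisting, a plasmablast-emitting subset of families and a small
    fraction of cells without a constant-region call.
    """

    seed: int = 0
    donor: str = "D1"
    n_families: int = 200
    zipf_alpha: float = 2.0
    max_family_size: int = 100
    # germline reference
    n_vh: int = 30
    n_jh: int = 6
    n_vk: int = 20
    n_jk: int = 5
    n_vl: int = 15
    n_jl: int = 4
    v_length: int = 210
    j_length: int = 24
    # junction model (lengths in nt, multiples of 3)
    heavy_junction_range: tuple[int, int] = (21, 60)
    light_junction_range: tuple[int, int] = (24, 36)
    # lineage model
    mutation_rate: float = 1.0   # Poisson mean nt mutations per heavy edge
    p_switch: float = 0.15       # per-edge probability of a class switch
    igd_family_fraction: float = 0.01  # families natively IgD (never by switching)
    kappa_fraction: float = 0.6
    # sampling model
    timepoints: tuple[object, ...] = (2014, 2020)
    p_persist: float = 0.7
    guarantee_persistence: bool = True
    pb_family_fraction: float = 0.3
    pb_cell_fraction: float = 0.25
    no_c_call_fraction: float = 0.05

    def validate(self) -> None:
        for name in ("p_switch", "igd_family_fraction", "kappa_fraction",
                     "p_persist", "pb_family_fraction", "pb_cell_fraction",
                     "no_c_call_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.zipf_alpha <= 1.0:
            raise ValueError("zipf_alpha must be > 1")
        if self.n_families < 1 or self.max_family_size < 1:
            raise ValueError("need at least one family of at least one cell")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be >= 0")

    def to_text(self) -> str:
        """key = value dump for the run manifest."""
        return "\n".join(
            f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)
        )


@dataclasses.dataclass
class TruthLineage:
    """True lineage of one family: node sequences, topology and switch events."""

    nodes: list[str]                       # node labels, root first
    parent: dict[str, str | None]          # node -> parent (root -> None)
    heavy_seq: dict[str, str]
    light_seq: dict[str, str]
    n_mut: dict[str, int]                  # heavy nt mutations on the edge into node
    isotype: dict[str, str]                # true isotype at node (before c-call dropout)
    switch_events: list[tuple[str, str, str]]  # (child node, from, to)
    leaf_cell: dict[str, str]              # leaf node -> cell barcode


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth for a simulated repertoire."""

    family_of: dict[str, str]              # cell -> true family id
    lineages: dict[str, TruthLineage]
    persistent: dict[str, bool]
    timepoint_of: dict[str, object]
    compartment_of: dict[str, str]
    ancestor_heavy: dict[str, tuple[str, str, str]]  # family -> (v gene, j gene, junction)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(NT, size=length))


def _hamming_str(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def make_reference(config: SimConfig) -> GermlineReference:
    """Random but reproducible per-locus V/J gene sets.

    Same-segment genes are kept pairwise >= 10 nt apart so that truth gene
    calls are unambiguous.
    """
    rng = np.random.default_rng(config.seed)

    def gene_set(prefix: str, n: int, length: int) -> dict[str, str]:
        genes: dict[str, str] = {}
        seqs: list[str] = []
        for i in range(1, n + 1):
            while True:
                s = _random_seq(rng, length)
                if all(_hamming_str(s, t) >= 10 for t in seqs):
                    break
            seqs.append(s)
            genes[f"{prefix}{i}-1"] = s
        return genes

    return GermlineReference(
        v={
            "IGH": gene_set("IGHV", config.n_vh, config.v_length),
            "IGK": gene_set("IGKV", config.n_vk, config.v_length),
            "IGL": gene_set("IGLV", config.n_vl, config.v_length),
        },
        j={
            "IGH": gene_set("IGHJ", config.n_jh, config.j_length),
            "IGK": gene_set("IGKJ", config.n_jk, config.j_length),
            "IGL": gene_set("IGLJ", config.n_jl, config.j_length),
        },
    )


def _random_junction(rng: np.random.Generator, lo: int, hi: int) -> str:
    """Random in-frame junction flanked by the conserved C and W codons."""
    length = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
    length = max(9, length)
    return "TGT" + _random_seq(rng, length - 6) + "TGG"


def _mutate(rng: np.random.Generator, seq: str, n: int) -> str:
    if n == 0:
        return seq
    chars = list(seq)
    positions = rng.choice(len(chars), size=min(n, len(chars)), replace=False)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(3))]
    return "".join(chars)


def _family_sizes(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    sizes = np.empty(config.n_families, dtype=int)
    for i in range(config.n_families):
        while True:
            s = int(rng.zipf(config.zipf_alpha))
            if s <= config.max_family_size:
                sizes[i] = s
                break
    return sizes


def simulate_repertoire(config: SimConfig) -> tuple[list[PairedCell], SyntheticTruth]:
    """Simulate one donor's paired-chain repertoire plus its ground truth.

    Each family grows a binary lineage from an unmutated VDJ ancestor:
    a uniformly chosen leaf splits into two children, each child edge adding
    Poisson(mutation_rate) heavy and Poisson(mutation_rate / 2) light nt
    mutations at uniform positions; the observed cells are the final leaves.
    Isotype starts at IGHM (IGHD for a small native-IgD fraction), switches on
    an edge with probability p_switch to a uniformly chosen strictly
    downstream class, and is inherited — irreversible by construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ref = make_reference(config)
    sizes = _family_sizes(rng, config)

    cells: list[PairedCell] = []
    truth = SyntheticTruth({}, {}, {}, {}, {}, {})

    for fi, size in enumerate(sizes, start=1):
        fam_id = f"T{fi:05d}"
        vh = str(rng.choice(sorted(ref.v["IGH"])))
        jh = str(rng.choice(sorted(ref.j["IGH"])))
        hj = _random_junction(rng, *config.heavy_junction_range)
        light_locus = "IGK" if rng.random() < config.kappa_fraction else "IGL"
        vl = str(rng.choice(sorted(ref.v[light_locus])))
        jl = str(rng.choice(sorted(ref.j[light_locus])))
        lj = _random_junction(rng, *config.light_junction_range)

        heavy_anc = ref.v["IGH"][vh] + hj + ref.j["IGH"][jh]
        light_anc = ref.v[light_locus][vl] + lj + ref.j[light_locus][jl]
        root_iso = "IGHD" if rng.random() < config.igd_family_fraction else "IGHM"

        lin = TruthLineage(
            nodes=["n0"], parent={"n0": None},
            heavy_seq={"n0": heavy_anc}, light_seq={"n0": light_anc},
            n_mut={"n0": 0}, isotype={"n0": root_iso},
            switch_events=[], leaf_cell={},
        )
        leaves = ["n0"]
        counter = 0
        while len(leaves) < size:
            pick = int(rng.integers(len(leaves)))
            node = leaves.pop(pick)
            for _ in range(2):
                counter += 1
                child = f"n{counter}"
                nh = int(rng.poisson(config.mutation_rate))
                nl = int(rng.poisson(config.mutation_rate / 2.0))
                iso = lin.isotype[node]
                if rng.random() < config.p_switch:
                    targets = downstream_classes(iso)
                    if targets:
                        new_iso = str(rng.choice(targets))
                        lin.switch_events.append((child, iso, new_iso))
                        iso = new_iso
                lin.nodes.append(child)
                lin.parent[child] = node
                lin.heavy_seq[child] = _mutate(rng, lin.heavy_seq[node], nh)
                lin.light_seq[child] = _mutate(rng, lin.light_seq[node], nl)
                lin.n_mut[child] = nh
                lin.isotype[child] = iso
                leaves.append(child)

        persistent = (
            len(config.timepoints) >= 2 and rng.random() < config.p_persist
        )
        tps = list(config.timepoints)
        if persistent and config.guarantee_persistence and len(leaves) >= 2:
            # force presence at two distinct timepoints, rest uniform
            cell_tps = [tps[0], tps[-1]] + [
                tps[int(rng.integers(len(tps)))] for _ in leaves[2:]
            ]
        elif persistent:
            cell_tps = [tps[int(rng.integers(len(tps)))] for _ in leaves]
        else:
            tp = tps[int(rng.integers(len(tps)))]
            cell_tps = [tp] * len(leaves)

        pb_family = rng.random() < config.pb_family_fraction
        germ_heavy = ref.v["IGH"][vh] + "N" * len(hj) + ref.j["IGH"][jh]
        germ_light = ref.v[light_locus][vl] + "N" * len(lj) + ref.j[light_locus][jl]

        for li, leaf in enumerate(leaves):
            cell_id = f"{fam_id}-{leaf}"
            lin.leaf_cell[leaf] = cell_id
            compartment = (
                "PB" if pb_family and rng.random() < config.pb_cell_fraction else "MBC"
            )
            tp = cell_tps[li]
            sample_id = f"{config.donor}_{tp}_{compartment}"
            iso = lin.isotype[leaf]
            if rng.random() < config.no_c_call_fraction:
                iso = NO_ISOTYPE
            heavy = ChainRecord(
                cell_id=cell_id, sample_id=sample_id, locus="IGH", productive=True,
                v_call=vh, j_call=jh,
                junction=lin.heavy_seq[leaf][config.v_length:config.v_length + len(hj)],
                isotype=iso,
                sequence_alignment=lin.heavy_seq[leaf],
                germline_alignment=germ_heavy,
                umi_count=int(rng.integers(200, 2000)) if compartment == "PB"
                else int(rng.integers(1, 30)),
            )
            light = ChainRecord(
                cell_id=cell_id, sample_id=sample_id, locus=light_locus,
                productive=True, v_call=vl, j_call=jl,
                junction=lin.light_seq[leaf][config.v_length:config.v_length + len(lj)],
                sequence_alignment=lin.light_seq[leaf],
                germline_alignment=germ_light,
                umi_count=int(rng.integers(1, 30)),
            )
            cells.append(PairedCell(
                cell_id=cell_id, sample_id=sample_id, donor=config.donor,
                timepoint=tp, compartment=compartment, heavy=heavy,
                kappa=light if light_locus == "IGK" else None,
                lambda_=light if light_locus == "IGL" else None,
            ))
            truth.family_of[cell_id] = fam_id
            truth.timepoint_of[cell_id] = tp
            truth.compartment_of[cell_id] = compartment
        truth.lineages[fam_id] = lin
        truth.persistent[fam_id] = persistent
        truth.ancestor_heavy[fam_id] = (vh, jh, hj)

    cells.sort(key=lambda c: c.cell_id)
    return cells, truth


def truth_partition(truth: SyntheticTruth) -> dict[str, str]:
    """The true cell -> family map, in the same shape as clone assignments."""
    return dict(truth.family_of)
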