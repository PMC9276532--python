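"""Shared fixtures and small construction helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from bcrclone import (
    ChainRecord,
    ClonalFamily,
    PairedCell,
    SimConfig,
    simulate_repertoire,
)

HJ = "TGTGCGAGAGATTACTGG"          # 18 nt heavy junction
LJ = "TGTCAACAGAGTTACTGG"          # 18 nt light junction


def make_chain(
    cell_id: str,
    locus: str = "IGH",
    junction: str = HJ,
    v: str | None = None,
    j: str | None = None,
    productive: bool = True,
    isotype: str = "none",
    sample_id: str = "S1",
    sequence_alignment: str | None = None,
    germline_alignment: str | None = None,
) -> ChainRecord:
    prefix = {"IGH": ("IGHV1-1", "IGHJ1-1"), "IGK": ("IGKV1-1", "IGKJ1-1"),
              "IGL": ("IGLV1-1", "IGLJ1-1")}[locus]
    return ChainRecord(
        cell_id=cell_id, sample_id=sample_id, locus=locus, productive=productive,
        v_call=v or prefix[0], j_call=j or prefix[1], junction=junction,
        isotype=isotype if locus == "IGH" else "none",
        sequence_alignment=sequence_alignment, germline_alignment=germline_alignment,
    )


def make_cell(
    cell_id: str,
    junction: str = HJ,
    v: str = "IGHV1-1",
    j: str = "IGHJ1-1",
    isotype: str = "IGHM",
    light_locus: str = "IGK",
    light_junction: str = LJ,
    light_v: str | None = None,
    light_j: str | None = None,
    sample_id: str = "S1",
    timepoint: object = 0,
    compartment: str = "MBC",
    donor: str = "D1",
    sequence_alignment: str | None = None,
    germline_alignment: str | None = None,
) -> PairedCell:
    heavy = make_chain(cell_id, "IGH", junction, v, j, True, isotype, sample_id,
                       sequence_alignment, germline_alignment)
    light = make_chain(cell_id, light_locus, light_junction, light_v, light_j,
                       True, "none", sample_id)
    return PairedCell(
        cell_id=cell_id, sample_id=sample_id, donor=donor, timepoint=timepoint,
        compartment=compartment, heavy=heavy,
        kappa=light if light_locus == "IGK" else None,
        lambda_=light if light_locus == "IGL" else None,
    )


def make_family(clone_id: str, cells: list[PairedCell]) -> ClonalFamily:
    """Assemble a ClonalFamily directly from cells (bypassing clustering)."""
    from collections import Counter

    from bcrclone.clonal_inference import _representative_heavy

    rep_heavy, rep_cell = _representative_heavy(cells)
    h = cells[0].heavy
    return ClonalFamily(
        clone_id=clone_id,
        members=list(cells),
        partition_key=(h.v_gene, h.j_gene, len(h.junction)),
        sample_counts=dict(Counter(c.sample_id for c in cells)),
        isotype_counts=dict(Counter(
            c.heavy.isotype for c in cells if c.heavy.isotype != "none")),
        mean_vh_mutation=None,
        representative_heavy=rep_heavy,
        representative_light=rep_cell.light,
    )


def random_junction(rng: np.random.Generator, length: int = 18) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def sim_default():
    """A mid-sized simulated repertoire with SHM on, shared across tests."""
    cfg = SimConfig(seed=7, n_families=80, mutation_rate=1.0)
    cells, truth = simulate_repertoire(cfg)
    return cfg, cells, truth


@pytest.fixture(scope="session")
def sim_no_shm():
    """Degenerate repertoire without somatic hypermutation."""
    cfg = SimConfig(seed=9, n_families=50, mutation_rate=0.0)
    cells, truth = simulate_repertoire(cfg)
    return cfg, cells, truth
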