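"""Chain-level table I/O, productive/pairing filters and germline reconstruction.

Reads AIRR Rearrangement TSV or 10X-style filtered-contig CSV into
:class:`ChainRecord` objects, assembles validated heavy+light
:class:`PairedCell` objects (one productive heavy chain paired with one κ
and/or one λ), and writes clone-annotated AIRR TSV back out so that a
write/read round-trip is the identity on all stored fields.

Coordinates are 0-based half-open internally; the AIRR TSV columns follow the
community standard's conventions on output.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .isotypes import NO_ISOTYPE, normalize_isotype

log = logging.getLogger(__name__)

LOCI = ("IGH", "IGK", "IGL")


class FormatError(ValueError):
    """A mandatory column is missing or a field cannot be parsed."""


class GermlineLookupError(LookupError):
    """A V or J gene call cannot be resolved in the germline reference."""


class AlignmentError(ValueError):
    """Sequence and germline lengths disagree under shared alignment coordinates."""


_ALLELE_RE = re.compile(r"\*.*$")


def gene_level(call: str) -> str:
    """Reduce a (possibly multi-valued) V/J call to a gene-level name.

    Takes the first comma-separated call, strips the allele suffix (``*01``)
    and a trailing locus-duplication letter (``IGHV1-69D`` -> ``IGHV1-69``).
    """
    first = call.split(",")[0].strip()
    gene = _ALLELE_RE.sub("", first)
    if len(gene) >= 2 and gene[-1] == "D" and gene[-2].isdigit():
        gene = gene[:-1]
    return gene


@dataclasses.dataclass
class ChainRecord:
    """One sequenced antibody chain (heavy or light) with its annotations."""

    cell_id: str
    sample_id: str
    locus: str
    productive: bool
    v_call: str
    j_call: str
    junction: str
    isotype: str = NO_ISOTYPE
    sequence_alignment: str | None = None
    germline_alignment: str | None = None
    umi_count: int = 0

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise FormatError(f"unknown locus {self.locus!r} for cell {self.cell_id}")
        if self.isotype != NO_ISOTYPE and self.locus != "IGH":
            raise FormatError(f"light chain {self.cell_id} carries isotype {self.isotype}")

    @property
    def cdr3(self) -> str:
        """Junction minus the flanking conserved codons (C ... W/F)."""
        return self.junction[3:-3]

    @property
    def v_gene(self) -> str:
        return gene_level(self.v_call)

    @property
    def j_gene(self) -> str:
        return gene_level(self.j_call)


@dataclasses.dataclass
class PairedCell:
    """A barcode's validated heavy chain plus one κ and/or one λ partner."""

    cell_id: str
    sample_id: str
    donor: str
    timepoint: object
    compartment: str
    heavy: ChainRecord
    kappa: ChainRecord | None = None
    lambda_: ChainRecord | None = None

    def __post_init__(self) -> None:
        if self.kappa is None and self.lambda_ is None:
            raise ValueError(f"cell {self.cell_id}: at least one light chain required")
        for ch in self.chains:
            if ch.cell_id != self.cell_id:
                raise ValueError(f"cell {self.cell_id}: member chain has cell_id {ch.cell_id}")
            if not ch.productive:
                raise ValueError(f"cell {self.cell_id}: non-productive member chain")

    @property
    def chains(self) -> list[ChainRecord]:
        return [c for c in (self.heavy, self.kappa, self.lambda_) if c is not None]

    @property
    def lights(self) -> list[ChainRecord]:
        return [c for c in (self.kappa, self.lambda_) if c is not None]

    @property
    def light(self) -> ChainRecord:
        """Preferred single light chain: κ if present, else λ."""
        return self.kappa if self.kappa is not None else self.lambda_  # type: ignore[return-value]


@dataclasses.dataclass
class GermlineReference:
    """Per-locus maps from gene name to germline nt sequence for V and J."""

    v: dict[str, dict[str, str]]
    j: dict[str, dict[str, str]]

    def get_v(self, locus: str, gene: str) -> str:
        try:
            return self.v[locus][gene]
        except KeyError:
            raise GermlineLookupError(f"V gene {gene!r} not in reference for locus {locus}") from None

    def get_j(self, locus: str, gene: str) -> str:
        try:
            return self.j[locus][gene]
        except KeyError:
            raise GermlineLookupError(f"J gene {gene!r} not in reference for locus {locus}") from None


# ---------------------------------------------------------------------------
# reading

_AIRR_MANDATORY = ("cell_id", "locus", "productive", "v_call", "j_call", "junction")
_CONTIG_MANDATORY = ("barcode", "chain", "productive", "v_gene", "j_gene", "cdr3_nt")

_TRUE = {"T", "TRUE", "1"}


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().upper() in _TRUE


def _read_table(path: str | Path, dialect: str) -> pd.DataFrame:
    sep = "\t" if dialect == "airr_tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        log.warning("empty input file: %s", path)
        return pd.DataFrame()
    return df


def read_chains(path: str | Path, dialect: str = "airr_tsv") -> list[ChainRecord]:
    """Read one :class:`ChainRecord` per row of an AIRR TSV or contig CSV.

    Multi-valued ``v_call`` strings are preserved verbatim; unknown
    constant-region calls map to isotype ``none``.
    """
    if dialect not in ("airr_tsv", "contig_csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _read_table(path, dialect)
    if df.empty:
        log.warning("no rows read from %s", path)
        return []
    mandatory = _AIRR_MANDATORY if dialect == "airr_tsv" else _CONTIG_MANDATORY
    for col in mandatory:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} for dialect {dialect}")

    records: list[ChainRecord] = []
    for row in df.itertuples(index=False):
        r = row._asdict()
        if dialect == "airr_tsv":
            rec = ChainRecord(
                cell_id=r["cell_id"],
                sample_id=r.get("sample_id", "") or "sample",
                locus=r["locus"],
                productive=_parse_bool(r["productive"]),
                v_call=r["v_call"],
                j_call=r["j_call"],
                junction=r["junction"],
                isotype=normalize_isotype(r.get("c_call", "")),
                sequence_alignment=r.get("sequence_alignment") or None,
                germline_alignment=r.get("germline_alignment") or None,
                umi_count=int(r.get("umi_count") or 0),
            )
        else:
            # 10X reports cdr3_nt spanning the conserved C..W/F codons,
            # i.e. the AIRR junction.
            rec = ChainRecord(
                cell_id=r["barcode"],
                sample_id=r.get("sample_id", "") or "sample",
                locus=r["chain"],
                productive=_parse_bool(r["productive"]),
                v_call=r["v_gene"],
                j_call=r["j_gene"],
                junction=r["cdr3_nt"],
                isotype=normalize_isotype(r.get("c_gene", "")),
                umi_count=int(r.get("umis") or 0),
            )
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# pairing filter

_DEFAULT_META = {"donor": "D1", "timepoint": 0, "compartment": "MBC"}


def filter_productive_paired(
    chains: Iterable[ChainRecord],
    sample_metadata: Mapping[str, Mapping[str, object]] | None = None,
    cell_metadata: Mapping[str, Mapping[str, object]] | None = None,
) -> tuple[list[PairedCell], dict[str, int]]:
    """Keep barcodes with exactly one productive heavy and one κ and/or one λ.

    Barcodes with more than one productive chain of any single locus are
    dropped as presumptive multiplets. Returns the kept cells (sorted by
    barcode) and a per-reason discard report.

    Metadata (donor/timepoint/compartment) is looked up per cell barcode
    first, then per sample_id, then defaults.
    """
    by_cell: dict[str, list[ChainRecord]] = defaultdict(list)
    for ch in chains:
        by_cell[ch.cell_id].append(ch)

    report = {
        "kept": 0,
        "no_productive_heavy": 0,
        "multiple_heavy": 0,
        "no_light": 0,
        "multiple_kappa": 0,
        "multiple_lambda": 0,
    }
    cells: list[PairedCell] = []
    for cell_id in sorted(by_cell):
        prod = [c for c in by_cell[cell_id] if c.productive]
        heavies = [c for c in prod if c.locus == "IGH"]
        kappas = [c for c in prod if c.locus == "IGK"]
        lambdas = [c for c in prod if c.locus == "IGL"]
        if len(heavies) == 0:
            report["no_productive_heavy"] += 1
            continue
        if len(heavies) > 1:
            report["multiple_heavy"] += 1
            continue
        if len(kappas) > 1:
            report["multiple_kappa"] += 1
            continue
        if len(lambdas) > 1:
            report["multiple_lambda"] += 1
            continue
        if not kappas and not lambdas:
            report["no_light"] += 1
            continue
        heavy = heavies[0]
        meta = dict(_DEFAULT_META)
        if sample_metadata and heavy.sample_id in sample_metadata:
            meta.update(sample_metadata[heavy.sample_id])
        if cell_metadata and cell_id in cell_metadata:
            meta.update(cell_metadata[cell_id])
        cells.append(
            PairedCell(
                cell_id=cell_id,
                sample_id=heavy.sample_id,
                donor=str(meta["donor"]),
                timepoint=meta["timepoint"],
                compartment=str(meta["compartment"]),
                heavy=heavy,
                kappa=kappas[0] if kappas else None,
                lambda_=lambdas[0] if lambdas else None,
            )
        )
        report["kept"] += 1
    return cells, report


# ---------------------------------------------------------------------------
# germline reconstruction

def reconstruct_germline(cell: PairedCell, ref: GermlineReference) -> dict[str, str]:
    """Rebuild the per-chain germline: V segment + N-masked junction + J segment.

    Returns a map locus -> germline string. The germline length must equal
    the chain's aligned sequence length under the same coordinates.
    """
    out: dict[str, str] = {}
    for ch in cell.chains:
        v = ref.get_v(ch.locus, ch.v_gene)
        j = ref.get_j(ch.locus, ch.j_gene)
        germ = v + "N" * len(ch.junction) + j
        if ch.sequence_alignment is not None and len(germ) != len(ch.sequence_alignment):
            raise AlignmentError(
                f"cell {cell.cell_id} {ch.locus}: germline length {len(germ)} != "
                f"sequence length {len(ch.sequence_alignment)}"
            )
        out[ch.locus] = germ
    return out


def apply_germlines(cells: Sequence[PairedCell], ref: GermlineReference) -> None:
    """Fill ``germline_alignment`` on every member chain, in place."""
    for cell in cells:
        germs = reconstruct_germline(cell, ref)
        for ch in cell.chains:
            ch.germline_alignment = germs[ch.locus]


# ---------------------------------------------------------------------------
# writing

_OUT_COLUMNS = (
    "cell_id", "sample_id", "donor", "timepoint", "compartment", "locus",
    "productive", "v_call", "j_call", "junction", "c_call",
    "sequence_alignment", "germline_alignment", "umi_count", "clone_id",
)


def write_airr(
    cells: Sequence[PairedCell],
    path: str | Path,
    assignments: Mapping[str, str] | None = None,
) -> None:
    """Write paired cells as AIRR-schema TSV, one row per chain.

    Adds sample/compartment metadata columns and, when *assignments* maps
    barcodes to clone ids, a ``clone_id`` column. An empty collection yields
    a header-only file.
    """
    rows = []
    for cell in cells:
        clone = assignments.get(cell.cell_id, "") if assignments else ""
        for ch in cell.chains:
            rows.append({
                "cell_id": cell.cell_id,
                "sample_id": cell.sample_id,
                "donor": cell.donor,
                "timepoint": cell.timepoint,
                "compartment": cell.compartment,
                "locus": ch.locus,
                "productive": "T" if ch.productive else "F",
                "v_call": ch.v_call,
                "j_call": ch.j_call,
                "junction": ch.junction,
                "c_call": "" if ch.isotype == NO_ISOTYPE else ch.isotype,
                "sequence_alignment": ch.sequence_alignment or "",
                "germline_alignment": ch.germline_alignment or "",
                "umi_count": ch.umi_count,
                "clone_id": clone,
            })
    df = pd.DataFrame(rows, columns=_OUT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_cells(path: str | Path) -> tuple[list[PairedCell], dict[str, int]]:
    """Read an AIRR TSV written by :func:`write_airr` back into paired cells.

    Per-cell donor/timepoint/compartment columns are honoured when present.
    Returns (cells, filter report); the clone_id column, if any, is ignored
    here (clustering owns clone assignment).
    """
    chains = read_chains(path, dialect="airr_tsv")
    df = _read_table(path, "airr_tsv")
    cell_meta: dict[str, dict[str, object]] = {}
    if not df.empty and "donor" in df.columns:
        for row in df.itertuples(index=False):
            r = row._asdict()
            tp: object = r.get("timepoint", 0)
            try:
                tp = int(tp)  # type: ignore[arg-type]
            except (TypeError, ValueError):
                pass
            cell_meta[r["cell_id"]] = {
                "donor": r.get("donor", "D1"),
                "timepoint": tp,
                "compartment": r.get("compartment", "MBC"),
            }
    return filter_productive_paired(chains, cell_metadata=cell_meta)
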