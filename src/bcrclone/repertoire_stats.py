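"""Repertoire-level statistics over clonal families.

Size waterfalls with dominant isotypes, class-switch propensity matrices,
Morisita-Horn overlap with subsampling, multi-year family-sharing
projections, convergent (public) clonotype detection between donors, and
gene-usage / CDR3-length summaries.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clonal_inference import ClonalFamily, junction_distance
from .io_airr import PairedCell
from .isotypes import ISOTYPE_ORDER, NO_ISOTYPE, isotype_rank

LARGE_FAMILY_CUTOFF = 6  # "more than six" vs "six or fewer" cells
DEFAULT_BINS = (1, 2, 6)  # upper edges -> bins 1, 2, 3-6, >6


# ---------------------------------------------------------------------------
# size distribution / dominant isotype

def dominant_isotype(family: ClonalFamily, dominant_fraction: float = 0.8) -> str:
    """Isotype carried by >= *dominant_fraction* of the family's isotype-determined
    cells; 'mixed' when no class reaches the fraction, 'none' when no cell has
    a determined isotype."""
    counts = family.isotype_counts
    total = sum(counts.values())
    if total == 0:
        return NO_ISOTYPE
    iso, top = min(counts.items(), key=lambda kv: (-kv[1], isotype_rank(kv[0])))
    return iso if top / total >= dominant_fraction else "mixed"


def size_waterfall(
    families: Sequence[ClonalFamily],
    dominant_fraction: float = 0.8,
    large_cutoff: int = LARGE_FAMILY_CUTOFF,
) -> pd.DataFrame:
    """Families ranked by descending size with dominant isotype and a marker
    separating families of more than *large_cutoff* cells."""
    rows = [
        {
            "rank": rank,
            "clone_id": f.clone_id,
            "size": f.size,
            "dominant_isotype": dominant_isotype(f, dominant_fraction),
            "large": f.size > large_cutoff,
        }
        for rank, f in enumerate(
            sorted(families, key=lambda f: (-f.size, f.clone_id)), start=1
        )
    ]
    return pd.DataFrame(rows, columns=["rank", "clone_id", "size", "dominant_isotype", "large"])


# ---------------------------------------------------------------------------
# class-switch propensity

def switch_propensity(families: Sequence[ClonalFamily]) -> pd.DataFrame:
    """Count clonal families per (upstream, downstream) isotype pair.

    For each family's set of distinct isotypes S (cells without a determined
    isotype ignored): |S| = 1 increments the diagonal; |S| >= 2 increments the
    (upstream, downstream) entry for every unordered pair, per genomic locus
    order. The strict lower triangle stays zero.
    """
    mat = pd.DataFrame(0, index=list(ISOTYPE_ORDER), columns=list(ISOTYPE_ORDER), dtype=int)
    for f in families:
        isotypes = sorted({iso for iso in f.isotype_counts}, key=isotype_rank)
        if not isotypes:
            continue
        if len(isotypes) == 1:
            mat.loc[isotypes[0], isotypes[0]] += 1
            continue
        for up, down in itertools.combinations(isotypes, 2):
            mat.loc[up, down] += 1
    return mat


# ---------------------------------------------------------------------------
# Morisita-Horn

def morisita_horn(x: Mapping[str, int] | pd.Series, y: Mapping[str, int] | pd.Series) -> float:
    """Morisita-Horn similarity between two per-family abundance vectors.

    C = 2 sum(x_i y_i) / ((sum(x_i^2)/X^2 + sum(y_i^2)/Y^2) * X * Y),
    indices aligned over the union of family ids; 0 = disjoint, 1 = proportional.
    """
    xs = pd.Series(x, dtype=float)
    ys = pd.Series(y, dtype=float)
    xs, ys = xs.align(ys, fill_value=0.0)
    if (xs < 0).any() or (ys < 0).any():
        raise ValueError("abundances must be non-negative")
    X, Y = xs.sum(), ys.sum()
    if X == 0 or Y == 0:
        raise ValueError("Morisita-Horn undefined for an empty sample")
    num = 2.0 * float((xs * ys).sum())
    den = (float((xs ** 2).sum()) / X ** 2 + float((ys ** 2).sum()) / Y ** 2) * X * Y
    return num / den


def abundance_vector(cells_or_clones: Iterable[str]) -> pd.Series:
    """Per-family cell counts from an iterable of clone ids (one per cell)."""
    counts = Counter(cells_or_clones)
    return pd.Series(counts, dtype=int).sort_index()


def similarity_analysis(
    sample_clones: Mapping[str, Sequence[str]],
    subsample_sizes: Sequence[int],
    n_reps: int,
    seed: int,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Subsampled Morisita-Horn indices within and between samples.

    *sample_clones* maps sample id -> clone id per cell. For every requested
    pair (default: all unordered pairs including self) and subsample size,
    cells are drawn without replacement *n_reps* times; intra-sample rows draw
    two independent subsamples from the same sample. Returns one row per
    replicate; aggregate with :func:`summarize_similarity`.
    """
    rng = np.random.default_rng(seed)
    names = sorted(sample_clones)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i:]]
    rows = []
    for a, b in pairs:
        ca = np.asarray(sample_clones[a], dtype=object)
        cb = np.asarray(sample_clones[b], dtype=object)
        for size in subsample_sizes:
            if size > len(ca) or size > len(cb):
                raise ValueError(
                    f"subsample size {size} exceeds sample size for pair ({a}, {b})"
                )
            for rep in range(n_reps):
                da = rng.choice(ca, size=size, replace=False)
                db = rng.choice(cb, size=size, replace=False)
                mh = morisita_horn(abundance_vector(da), abundance_vector(db))
                rows.append({
                    "sample_a": a, "sample_b": b,
                    "type": "intra" if a == b else "inter",
                    "size": size, "rep": rep, "morisita_horn": mh,
                })
    return pd.DataFrame(rows)


def summarize_similarity(table: pd.DataFrame) -> pd.DataFrame:
    """Median and min-max of the index per pair/size across replicates."""
    g = table.groupby(["sample_a", "sample_b", "type", "size"])["morisita_horn"]
    out = g.agg(median="median", min="min", max="max").reset_index()
    return out


# ---------------------------------------------------------------------------
# multi-timepoint sharing

def _bin_labels(bins: Sequence[int]) -> list[str]:
    labels = []
    lo = 1
    for ub in bins:
        labels.append(str(ub) if lo == ub else f"{lo}-{ub}")
        lo = ub + 1
    labels.append(f">{bins[-1]}")
    return labels


def _bin_of(size: int, bins: Sequence[int], labels: Sequence[str]) -> str:
    for ub, lab in zip(bins, labels):
        if size <= ub:
            return lab
    return labels[-1]


def project_families(
    families: Sequence[ClonalFamily],
    ref_sample: str,
    query_sample: str,
    bins: Sequence[int] = DEFAULT_BINS,
) -> pd.DataFrame:
    """Fraction of reference-sample families also present in the query sample,
    binned by the family's reference-sample size.

    Requires families built on pooled clustering of both samples: a family is
    shared iff the same clone has at least one cell in each sample.
    """
    if list(bins) != sorted(set(bins)):
        raise ValueError("bins must be strictly increasing")
    known = set()
    for f in families:
        known.update(f.sample_counts)
    for s in (ref_sample, query_sample):
        if s not in known:
            raise ValueError(f"unknown sample id {s!r}")
    labels = _bin_labels(bins)
    totals = Counter()
    shared = Counter()
    for f in families:
        ref_n = f.sample_counts.get(ref_sample, 0)
        if ref_n == 0:
            continue
        lab = _bin_of(ref_n, bins, labels)
        totals[lab] += 1
        if f.sample_counts.get(query_sample, 0) > 0:
            shared[lab] += 1
    rows = []
    for lab in labels:
        tot = totals[lab]
        sh = shared[lab]
        rows.append({
            "bin": lab,
            "total": tot,
            "shared": sh,
            "percent_shared": 100.0 * sh / tot if tot else float("nan"),
        })
    return pd.DataFrame(rows, columns=["bin", "total", "shared", "percent_shared"])


# ---------------------------------------------------------------------------
# convergent clonotypes

@dataclasses.dataclass
class ConvergencePair:
    """A candidate convergent family pair with per-chain CDR3 identities."""

    family_a: str
    family_b: str
    heavy_identity: float
    light_identity: float
    shared: bool


def find_convergent(
    families_a: Sequence[ClonalFamily],
    families_b: Sequence[ClonalFamily],
    identity_min: float = 0.85,
    chains: str = "both",
) -> list[ConvergencePair]:
    """Convergent clonotypes between two repertoires.

    A pair is a candidate when heavy and light V and J genes are identical and
    both chains' CDR3 lengths match; it is *shared* when the CDR3 nucleotide
    identity (1 - junction distance of the CDR3s) strictly exceeds
    *identity_min* on both chains ('both') or the heavy chain only ('heavy').
    Family representatives are the modal heavy junction's cell and its light
    partner.
    """
    if chains not in ("both", "heavy"):
        raise ValueError("chains must be 'both' or 'heavy'")
    # index B families by the gene/length gate for an O(n) scan
    index: dict[tuple, list[ClonalFamily]] = {}
    for fb in families_b:
        hb, lb = fb.representative_heavy, fb.representative_light
        key = (hb.v_gene, hb.j_gene, len(hb.cdr3),
               lb.locus, lb.v_gene, lb.j_gene, len(lb.cdr3))
        index.setdefault(key, []).append(fb)
    out: list[ConvergencePair] = []
    for fa in families_a:
        ha, la = fa.representative_heavy, fa.representative_light
        key = (ha.v_gene, ha.j_gene, len(ha.cdr3),
               la.locus, la.v_gene, la.j_gene, len(la.cdr3))
        for fb in index.get(key, ()):  # gene and length gates already hold
            hb, lb = fb.representative_heavy, fb.representative_light
            h_id = 1.0 - junction_distance(ha.cdr3, hb.cdr3)
            l_id = 1.0 - junction_distance(la.cdr3, lb.cdr3)
            if chains == "both":
                shared = h_id > identity_min and l_id > identity_min
            else:
                shared = h_id > identity_min
            out.append(ConvergencePair(fa.clone_id, fb.clone_id, h_id, l_id, shared))
    return out


# ---------------------------------------------------------------------------
# gene usage and CDR3 lengths

_SEGMENTS = {
    "VH": ("heavy", "v_gene"), "JH": ("heavy", "j_gene"),
    "VK": ("kappa", "v_gene"), "JK": ("kappa", "j_gene"),
    "VL": ("lambda_", "v_gene"), "JL": ("lambda_", "j_gene"),
}


def gene_usage(cells: Sequence[PairedCell], segment: str) -> pd.Series:
    """Gene-level usage frequencies for one segment; frequencies sum to 1.

    Light-chain segments count only cells carrying that locus.
    """
    try:
        attr, field = _SEGMENTS[segment]
    except KeyError:
        raise ValueError(f"unknown segment {segment!r}; one of {sorted(_SEGMENTS)}") from None
    genes = []
    for cell in cells:
        chain = getattr(cell, attr)
        if chain is not None:
            genes.append(getattr(chain, field))
    counts = pd.Series(Counter(genes), dtype=float).sort_index()
    return counts / counts.sum() if counts.sum() else counts


def cdr3_length_distribution(
    cells: Sequence[PairedCell] | None = None,
    families: Sequence[ClonalFamily] | None = None,
) -> pd.Series:
    """Histogram of heavy CDR3 nt lengths; per cell, or one vote per family
    (its representative) when *families* is given."""
    if (cells is None) == (families is None):
        raise ValueError("pass exactly one of cells or families")
    if cells is not None:
        lengths = [len(c.heavy.cdr3) for c in cells]
    else:
        lengths = [len(f.representative_heavy.cdr3) for f in families]
    return pd.Series(Counter(lengths), dtype=int).sort_index()
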