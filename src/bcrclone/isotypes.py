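"""Human IGH constant-region classes in genomic locus order.

Class-switch recombination deletes the DNA between the expressed constant
gene and a downstream one, so along any B-cell lineage the isotype can only
move rightwards in this order — the irreversibility that the switch-propensity
matrix and the simulator both rely on.
"""

from __future__ import annotations

#: 5'->3' order of the human IGH constant-region genes.
ISOTYPE_ORDER: tuple[str, ...] = (
    "IGHM",
    "IGHD",
    "IGHG3",
    "IGHG1",
    "IGHA1",
    "IGHG2",
    "IGHG4",
    "IGHE",
    "IGHA2",
)

#: Sentinel for chains without a constant-region call.
NO_ISOTYPE = "none"

_RANK = {iso: i for i, iso in enumerate(ISOTYPE_ORDER)}

_ALIASES = {
    "IGM": "IGHM", "IGD": "IGHD", "IGE": "IGHE",
    "IGG1": "IGHG1", "IGG2": "IGHG2", "IGG3": "IGHG3", "IGG4": "IGHG4",
    "IGA1": "IGHA1", "IGA2": "IGHA2",
}


def isotype_rank(isotype: str) -> int:
    """Locus-order rank of an isotype (0 = IGHM). Raises for unknown labels."""
    try:
        return _RANK[isotype]
    except KeyError:
        raise ValueError(f"unknown isotype label: {isotype!r}") from None


def normalize_isotype(c_call: object) -> str:
    """Map a constant-region call to a canonical class label.

    Unknown or missing strings (light-chain constants, NaN, '') map to
    :data:`NO_ISOTYPE` — cells without a determined isotype are retained
    downstream but excluded from isotype counts.
    """
    if c_call is None:
        return NO_ISOTYPE
    s = str(c_call).strip().upper()
    if not s or s == "NAN":
        return NO_ISOTYPE
    # allele suffixes on constant calls, e.g. IGHG1*01
    s = s.split("*")[0]
    if s in _RANK:
        return s
    return _ALIASES.get(s, NO_ISOTYPE)


def downstream_classes(isotype: str, allow_ighd: bool = False) -> tuple[str, ...]:
    """Classes strictly downstream of *isotype* in the locus (switch targets).

    IGHD is excluded by default: IgD is co-expressed with IgM by alternative
    splicing, not reached by switching.
    """
    r = isotype_rank(isotype)
    out = ISOTYPE_ORDER[r + 1:]
    if not allow_ighd:
        out = tuple(c for c in out if c != "IGHD")
    return out
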