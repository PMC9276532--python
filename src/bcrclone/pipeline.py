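"""End-to-end orchestration: filter, cluster, correct, summarize, draw.

Every stage reads and writes plain files (AIRR TSV, tidy TSV, newick, SVG)
so stages can be re-run or inspected independently; a JSON manifest records
the configuration, seed and per-stage record counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .clonal_inference import (
    ClonalFamily,
    ClonePartition,
    DEFAULT_THRESHOLD,
    build_families,
    cluster_clones,
    estimate_threshold,
    nearest_neighbor_distances,
    refine_by_light_chain,
)
from .honeycomb import layout_families, render_svg
from .io_airr import PairedCell, read_cells, write_airr
from .lineage import annotate_isotype_branches, build_tree, collapse_identical
from .repertoire_stats import (
    DEFAULT_BINS,
    project_families,
    similarity_analysis,
    size_waterfall,
    summarize_similarity,
    switch_propensity,
)

log = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_path: str
    out_dir: str
    dialect: str = "airr_tsv"
    threshold: float | str = "estimate"  # 'estimate' or a fixed fraction
    identity_min: float = 0.85
    dominant_fraction: float = 0.8
    bins: Sequence[int] = DEFAULT_BINS
    subsample_sizes: Sequence[int] = (50, 200)
    n_reps: int = 20
    tree_min_size: int = 5
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.identity_min <= 1.0:
            raise ValueError("identity_min must be in (0, 1]")
        if not 0.0 < self.dominant_fraction <= 1.0:
            raise ValueError("dominant_fraction must be in (0, 1]")
        if list(self.bins) != sorted(set(self.bins)):
            raise ValueError("bins must be strictly increasing")
        if isinstance(self.threshold, str) and self.threshold != "estimate":
            raise ValueError("threshold must be 'estimate' or a number")


def infer_clones(
    cells: Sequence[PairedCell],
    threshold: float | str = "estimate",
) -> tuple[ClonePartition, list[ClonalFamily]]:
    """Cluster heavy chains, apply the light-chain correction, build families."""
    if threshold == "estimate":
        nn = nearest_neighbor_distances(cells)
        t = estimate_threshold(nn, default=DEFAULT_THRESHOLD)
    else:
        t = float(threshold)
    partition = refine_by_light_chain(cluster_clones(cells, t), cells)
    return partition, build_families(partition, cells)


def families_table(families: Sequence[ClonalFamily]) -> pd.DataFrame:
    rows = []
    for f in families:
        rows.append({
            "clone_id": f.clone_id,
            "size": f.size,
            "v_gene": f.partition_key[0],
            "j_gene": f.partition_key[1],
            "junction_length": f.partition_key[2],
            "samples": ";".join(f"{k}:{v}" for k, v in sorted(f.sample_counts.items())),
            "isotypes": ";".join(f"{k}:{v}" for k, v in sorted(f.isotype_counts.items())),
            "mean_vh_mutation_pct": "" if f.mean_vh_mutation is None
            else round(f.mean_vh_mutation, 4),
        })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage on one input file; returns the output directory.

    Aborts with a stage-tagged error and a machine-readable error report on
    the first failing stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "seed": config.seed,
        "version": __version__,
        "counts": {},
    }
    stage = "read"
    try:
        cells, report = read_cells(config.input_path)
        manifest["counts"]["cells_paired"] = len(cells)
        manifest["counts"]["filter_report"] = report
        write_airr(cells, out / "paired.airr.tsv")

        stage = "cluster"
        partition, families = infer_clones(cells, config.threshold)
        manifest["counts"]["cells_clustered"] = len(partition.assignments)
        manifest["counts"]["families"] = len(families)
        manifest["threshold_used"] = partition.threshold_used
        write_airr(cells, out / "clones.airr.tsv", assignments=partition.assignments)
        families_table(families).to_csv(out / "families.tsv", sep="\t", index=False)

        stage = "stats"
        size_waterfall(families, config.dominant_fraction).to_csv(
            out / "waterfall.tsv", sep="\t", index=False)
        switch_propensity(families).to_csv(out / "switch_matrix.csv")
        samples = sorted({c.sample_id for c in cells})
        assignments = partition.assignments
        sample_clones = {
            s: [assignments[c.cell_id] for c in cells if c.sample_id == s]
            for s in samples
        }
        for i, ref_s in enumerate(samples):
            for query_s in samples[i + 1:]:
                tbl = project_families(families, ref_s, query_s, config.bins)
                tbl.to_csv(out / f"sharing_{ref_s}_vs_{query_s}.tsv",
                           sep="\t", index=False)
        sizes = [s for s in config.subsample_sizes
                 if all(s <= len(v) for v in sample_clones.values())]
        if sizes and len(samples) >= 1:
            sim = similarity_analysis(sample_clones, sizes, config.n_reps, config.seed)
            sim.to_csv(out / "similarity.tsv", sep="\t", index=False)
            summarize_similarity(sim).to_csv(
                out / "similarity_summary.tsv", sep="\t", index=False)

        stage = "trees"
        tree_dir = out / "trees"
        tree_dir.mkdir(exist_ok=True)
        n_trees = 0
        for fam in families:
            if fam.size < config.tree_min_size:
                continue
            heavy = fam.members[0].heavy
            if not heavy.sequence_alignment or not heavy.germline_alignment:
                continue
            variants = collapse_identical(fam)
            tree = annotate_isotype_branches(
                build_tree(variants, heavy.germline_alignment))
            (tree_dir / f"{fam.clone_id}.nwk").write_text(tree.to_newick() + "\n")
            n_trees += 1
        manifest["counts"]["trees"] = n_trees

        stage = "layout"
        layout = layout_families(families)
        layout.to_tsv(out / "honeycomb.tsv")
        render_svg(layout, out / "honeycomb.svg")
    except Exception as exc:
        (out / "error.json").write_text(json.dumps(
            {"stage": stage, "error": str(exc), "type": type(exc).__name__}, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
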