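# bcrclone

Paired single-cell B-cell receptor (BCR) repertoire analysis: clonal family
inference with light-chain correction, germline-rooted lineage trees,
repertoire stability and isotype-switch statistics, honeycomb visualisation,
and a ground-truth simulator that makes every stage testable end to end.

It is written for immunologists and computational biologists working with
single-cell V(D)J data (10X-style filtered-contig tables or AIRR
Rearrangement TSV) who want a reproducible, scriptable pipeline from
chain-level tables to family-level biology: which clonal families dominate a
memory B-cell pool, how stable they are across years, how they switch
isotype, and whether two donors share convergent (public) clonotypes.

## The model

**Clonal families.** Cells descend from one VDJ recombination event iff they
share heavy-chain V gene, J gene and junction length, and their junctions are
close. Within each (V<sub>H</sub>, J<sub>H</sub>, junction-length) group,
single-linkage hierarchical clustering on the length-normalized junction
Hamming distance *d*(a,b) = #mismatches / #compared positions (N positions
excluded) is cut at a threshold *t*. The threshold is estimated per dataset
as the valley of the distance-to-nearest-neighbour density (Gaussian KDE,
Silverman bandwidth, minimum between the two main modes), falling back to
the conventional operating value *t* = 0.15 when the distribution is not
bimodal. Heavy clones are then corrected with the light chains: cells of a
heavy clone are split into connected components of the "shares a light-chain
group (locus, V<sub>L</sub>, J<sub>L</sub>, junction length)" graph.

**Lineages.** Cells with identical V-region sequences collapse into
variants; a germline-rooted minimum-spanning-tree parsimony heuristic (with
zero-gain ancestral splices) connects them, labelling each branch with its
nucleotide and amino-acid mutation counts.

**Repertoire statistics.** Size waterfalls with the dominant (≥80% of
isotype-determined cells) class; class-switch propensity matrices counting
families per (upstream, downstream) isotype pair in IGH locus order
(M, D, G3, G1, A1, G2, G4, E, A2); multi-year family sharing binned by
family size (1, 2, 3–6, >6); abundance overlap via the Morisita–Horn index

&nbsp;&nbsp;&nbsp;&nbsp;C = 2·Σxᵢyᵢ / ((Σxᵢ²/X² + Σyᵢ²/Y²)·X·Y)

with subsampling; and convergent clonotypes between donors under strict
criteria (identical V/J genes on both chains, equal CDR3 lengths, >85% CDR3
nucleotide identity on both chains).

**Simulator.** Zipf family sizes, binary lineage growth with Poisson(λ)
mutations per edge, irreversible downstream isotype switching, κ/λ pairing,
multi-timepoint persistence and memory/plasmablast compartments — with the
full ground truth (cell→family map, lineage topologies, switch events)
recorded for validation.

## Worked example

```bash
python examples/01_simulate_and_cluster.py
```

```
simulated 429 paired cells in 150 true families
estimated junction-distance threshold: 0.359 (valley of the distance-to-nearest density; 0.15 fallback)
inferred 150 families; adjusted Rand index vs truth = 1.000
an ARI of 1.0 means the inferred partition matches the simulated clonal structure exactly
```

The threshold is the density valley separating clonally related junction
pairs (near 0) from unrelated ones; with it, clustering plus light-chain
correction recovers the simulated partition exactly (adjusted Rand index 1.0).
The other examples cover stability projections and Morisita–Horn overlap
(`02`), lineage trees (`03`), isotype waterfalls and switch matrices (`04`),
and convergence plus the honeycomb layout (`05`).

The same stages are available from the shell:

```bash
bcrclone simulate --seed 1 --n-families 150 --out run/sim
bcrclone cluster --input run/sim/simulated.airr.tsv --threshold 0.15 --out run/clones.airr.tsv
bcrclone report --input run/sim/simulated.airr.tsv --out run/full --seed 1
```

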