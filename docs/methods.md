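# Methods

## Problem and scope

Single-cell V(D)J sequencing yields, per cell barcode, a heavy chain and one
or two light chains with gene annotations, junction sequences and a
constant-region (isotype) call. This package reconstructs the clonal
structure of such a repertoire — families of cells descending from one VDJ
recombination event — and the family-level biology built on it: lineage
trees with per-branch mutation counts, multi-year stability, class-switch
propensity, abundance overlap between samples, convergent clonotypes between
donors, and a honeycomb visualisation. Annotation itself (alignment of raw
contigs to germline databases) is out of scope: inputs are already-annotated
chain tables.

## Input filtering

Only productive chains are considered. A barcode enters the analysis iff it
has exactly one productive heavy chain and exactly one productive κ and/or
exactly one productive λ. Barcodes with more than one productive chain of
any single locus are discarded as presumptive multiplets — the conservative
reading of "one κ and/or one λ"; discard reasons are counted in a report.
Cells whose heavy chain lacks a constant-region call keep isotype `none`;
they are retained everywhere but excluded from isotype counts, dominant-
isotype denominators and switch matrices.

Gene-level matching strips the allele suffix (`*01`) and a trailing
locus-duplication letter (`IGHV1-69D` → `IGHV1-69`); multi-valued calls use
the first listed gene. Internally all intervals are 0-based half-open; AIRR
TSV output follows the community standard's conventions. The 10X contig
dialect's `cdr3_nt` spans the conserved C…W/F codons and is therefore read
as the AIRR junction; CDR3 = junction minus the two flanking codons.

## Clonal inference

Distances are length-normalized Hamming distances between equal-length
junctions; positions where either sequence has N are excluded from numerator
and denominator. Cells are partitioned by (heavy V gene, J gene, junction
length); within each partition, single-linkage agglomerative clustering is
cut at distance ≤ t. Single linkage matches the behaviour of the standard
hierarchical-clustering toolchain for clone definition and makes the cut
equivalent to connected components over all pairs at distance ≤ t — the
property the test suite exploits with an independent union-find oracle.

The threshold t is the valley of the distance-to-nearest-neighbour density:
a Gaussian KDE with Silverman bandwidth is evaluated on a 0.001 grid, and
the minimum between the two highest local maxima is returned if it lies in
(0.02, 0.45). Degenerate inputs (empty, constant, unimodal, valley outside
the window) fall back to the fixed operating value 0.15, which can also be
forced. Both modes are exposed because re-estimating per dataset and fixing
one value per donor are both defensible; the fallback makes the estimator
total.

The light-chain correction splits each heavy clone into connected components
of the graph linking two cells iff they share at least one light-chain group
(locus, V gene, J gene, junction length). Grouping uses V/J genes and length
only — no second distance threshold — mirroring the granularity of the
standard light-chain correction. Cells carrying both κ and λ keep both
chains and can bridge components. The operation only ever splits clones and
is idempotent. Clone identifiers are re-derived deterministically (groups
sorted by partition key, then smallest member barcode), so repeated runs are
bit-identical.

## Lineage trees

Cells with identical heavy V-region alignments (optionally heavy+light
concatenations) collapse into variants with multiplicities. Trees are built
by a parsimony heuristic: a complete graph over {germline} ∪ variants with
Hamming weights (N/gap positions skipped), a minimum spanning tree grown
from the germline (Prim's algorithm with lexicographic tie-breaks), oriented
away from the root, followed by zero-gain splices — when a sibling's
mutation set is a strict subset of a variant's and the distances are
collinear, the variant is re-attached below that sibling, placing ancestral
variants on the path to their descendants. This replaces maximum-likelihood
tree programs deliberately: the downstream content (branch nt/aa mutation
counts, isotype placement, multiplicities) is preserved while substitution
models and ancestral-state inference stay out of scope. Branch labels are
Hamming distances between the *observed* endpoint sequences, not inferred
intermediates; the convention is stated here and carried in the exports.
Amino-acid counts translate the alignment in frame 0, skipping codons with
N or gaps. On two variants the heuristic provably attains the optimum
(the MST minimum coincides with the best of the three rooted topologies);
on larger instances the tests check the star-tree upper bound, the
distinct-mutated-column lower bound, and agreement with exhaustive search.

## Repertoire statistics

* **Dominant isotype**: the class carried by ≥ 80% (inclusive) of the
  family's isotype-determined cells; `mixed` below that; undetermined cells
  are excluded from the denominator, matching figures that mark such cells
  separately rather than counting them against dominance.
* **Switch propensity**: per family, the set of distinct isotypes S
  (determined only). |S| = 1 increments the diagonal; otherwise every
  unordered pair increments the (upstream, downstream) entry per the IGH
  locus order M, D, G3, G1, A1, G2, G4, E, A2. Irreversibility of
  class-switch recombination makes the strict lower triangle structurally
  zero. IgM and IgD are distinct classes (rare native IgD families exist).
* **Morisita–Horn**: C = 2Σxy / ((Σx²/X² + Σy²/Y²)XY) over the union of
  family ids; undefined (error) for empty samples. Subsampled comparisons
  draw cells without replacement; intra-sample rows draw two independent
  subsamples of the same sample, giving the re-sampling ceiling against
  which inter-sample values are judged.
* **Sharing projection**: with families clustered on the pooled multi-sample
  dataset, a reference-sample family is shared iff the same clone has ≥ 1
  cell in the query sample; families are binned by reference-sample size as
  1, 2, 3–6, >6 (the residual 3–6 bin is configurable; >6 follows the
  "more than six cells" convention for large families).
* **Convergence**: family representatives are the modal heavy junction's
  cell (ties → lexicographic, then smallest barcode) and its light partner
  (κ preferred). A pair is convergent iff V and J genes match on both
  chains, CDR3 lengths match on both chains, and CDR3 nucleotide identity
  (1 − junction distance of the CDR3s) strictly exceeds 85% — on both
  chains by default, heavy-only as an option, the default being the stricter
  reading of "in both heavy and light chains".

## Honeycomb layout

Families sorted by descending size are packed as contiguous blobs of hexes
on the axial (pointy-top) grid: each family seeds at the lowest free index
of the standard hex spiral and grows greedily toward the lowest-index free
neighbour; after placement the blob's border is blocked, giving one hex of
padding between families. Because spiral index is monotone in radius and a
seed is always the lowest free index, the minimum radius of successive
families never decreases — size ranking runs center → periphery. The exact
packing of the original honeycomb tool is unspecified, so this deterministic
spiral-blob scheme is the package's own reproducible stand-in preserving the
stated semantics (size ranking, per-cell isotype colouring, 'x' for
undetermined isotype).

## Simulator

The generator defines the study conditions for all validation. Defaults:
200 families with Zipf(α = 2) sizes truncated at 100; a random germline
reference (30/6 heavy V/J, 20/5 κ, 15/4 λ genes; V 210 nt, J 24 nt, gene
pairs ≥ 10 nt apart so truth gene calls are unambiguous); in-frame junctions
flanked by the conserved C/W codons, heavy 21–60 nt, light 24–36 nt;
binary lineage growth (a uniformly chosen leaf splits; observed cells are
the final leaves) with Poisson(λ = 1) heavy-chain and Poisson(λ/2)
light-chain mutations per edge at uniform positions — lights accumulate
fewer mutations, and the 1:0.5 split is this package's choice; per-edge
switch probability 0.15 to a uniformly chosen strictly-downstream class,
never to IgD (IgD families arise natively in 1% of families instead);
κ:λ = 60:40; two timepoints with persistence probability 0.7; 30% of
families emit plasmablasts (25% of their cells, with high UMI counts);
5% of cells lack a constant-region call.

Persistent families are guaranteed to appear at two distinct timepoints
(first two cells pinned); a `guarantee_persistence=False` mode assigns
cells i.i.d. uniformly instead, which is the size-independent sampling
regime under which percent-shared rises with family size — the qualitative
size effect the sharing tests check.

What the simulator does **not** emulate: real VDJ recombination biology
(RSS, TdT profiles, D genes), SHM hot/cold spots, selection, indels,
alignment gaps, annotation errors, or doublets. Passing tests therefore
demonstrate correctness of the inference machinery under clean annotations
and uniform SHM, not robustness to annotation noise; on real data the
clustering threshold and the light-chain correction carry more weight than
they do here.

## Numerical and design choices

* All randomness flows through `numpy.random.default_rng` from a single
  seed; equal seeds give byte-identical AIRR/TSV outputs.
* Distances compare with ≤ at the threshold; identity with strict > at the
  convergence cutoff (the published criteria word them that way).
* Junction masking: reconstructed germlines carry N over the junction, so
  mutation frequencies against them exclude the junction automatically.
* Degenerate inputs: empty chain files parse to empty lists with a warning;
  empty collections write header-only files; singleton distance groups are
  flagged absent rather than 0; Morisita–Horn on an empty sample raises.
* Problem sizes in tests and the acceptance script (60–500 families,
  ~100–1500 cells, 100 threshold replicates) are chosen as the smallest
  sizes at which the statistical checks are stable across seeds.

## Known limitations

* The parsimony heuristic can miss the optimum on ≥ 3 variants (tests bound
  it, and require optimality only where exhaustive search is feasible).
* Junction-length partitioning cannot merge clones whose members differ by
  indels in the junction.
* The threshold estimator assumes a bimodal distance-to-nearest density;
  sparse repertoires fall back to 0.15.
* Convergence matches family representatives, not all member pairs; a
  family whose modal junction is atypical may be missed.
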