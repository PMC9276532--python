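"""Isotype structure of the repertoire: waterfall and switch propensity.

Ranks families by size with their dominant (>= 80% of determined cells)
isotype, and counts families containing each (upstream, downstream) isotype
pair — the class-switch propensity matrix, whose strict lower triangle is
empty because switching is irreversible along the IGH locus.
"""

from bcrclone import SimConfig, simulate_repertoire, size_waterfall, switch_propensity
from bcrclone.pipeline import infer_clones

cells, _ = simulate_repertoire(SimConfig(seed=3, n_families=200, p_switch=0.25))
_, families = infer_clones(cells, threshold=0.15)

waterfall = size_waterfall(families)
print("ten largest families (dominant isotype = class carried by >=80% of "
      "isotype-determined cells; 'mixed' otherwise):")
print(waterfall.head(10).to_string(index=False))
n_large = int(waterfall["large"].sum())
print(f"{n_large} families have more than six cells\n")

matrix = switch_propensity(families)
print("switch propensity (rows upstream, columns downstream; diagonal = "
      "single-isotype families):")
print(matrix.loc[matrix.sum(axis=1) > 0, matrix.sum(axis=0) > 0].to_string())
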