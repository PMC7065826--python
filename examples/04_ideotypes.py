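"""Ideotype design and derivative-genotype simulation.

Rebuilds the ten ideotypes encoded in the bundled region table: ideotype 1
fixes the favorable allele in all 21 regions; ideotypes 2..10 successively
release the flour-redness (Fla) regions in ascending order of variance
contribution, keeping every flour-yield (FlYd) region fixed.  500 derivative
genotypes per ideotype are sampled from the conditional DH Markov chain, and
their traits predicted from the bundled multifamily QTL effects.
"""

import numpy as np

from mfqtl import (
    IntervalGrid,
    PredictionModel,
    build_ideotypes,
    generate_genotypes,
    predict_ideotype_phenotypes,
    regions_from_table,
)
from mfqtl.refdata import load_ideotype_regions, load_multifamily_qtls
from mfqtl.simulate import default_wheat_chromosomes

grid = IntervalGrid.from_lengths(default_wheat_chromosomes())
qtls = load_multifamily_qtls()
regions = regions_from_table(load_ideotype_regions(), qtls, grid)
specs = build_ideotypes(regions, n_ideotypes=10)
print(f"{len(regions)} regions -> {len(specs)} ideotypes")

# per-trait prediction weights: each reference QTL puts intensity * effect
# at its interval
models = {}
for trait in ("FlYd", "Fla"):
    w = np.zeros(grid.m)
    for _, row in qtls[qtls["trait"] == trait].iterrows():
        iv = grid.interval_of(str(row["chromosome"]), float(row["position_cm"]))
        w[iv] += float(row["intensity"]) * float(row["effect"])
    models[trait] = PredictionModel(m=grid.m, weights=w, mu_grand=0.0,
                                    mu_by_family={})

sets = {
    s.label: generate_genotypes(s, grid, n=500, seed=40 + s.label) for s in specs
}
table = predict_ideotype_phenotypes(sets, models)
summary = (
    table.pivot_table(index="ideotype", columns="trait", values="value",
                      aggfunc="mean")
    .round(3)
)
print(summary.to_string())
# read the values as deviations from an all-average genome: FlYd stays high
# for every ideotype (its regions are never released), while Fla relaxes
# towards the common parent as more redness regions are freed
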