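"""Posterior-weighted genomic prediction and cross-validation.

Trains the scan on a synthetic two-QTL study and reports 6-fold
cross-validated prediction accuracy: each interval contributes
p_l * u_l * a_l to the prediction, so accuracy tracks how much variance the
mapped QTLs explain.
"""

from mfqtl import (
    ChainConfig,
    IntervalGrid,
    QTLSpec,
    SimulationConfig,
    adjust_for_environment,
    crossvalidate,
    impute_interval_genotypes,
    simulate_dataset,
)

config = SimulationConfig(
    n_families=3,
    lines_per_family=100,
    chromosomes=[("1", 100.0), ("2", 100.0)],
    marker_spacing_cm=5.0,
    qtls=[
        QTLSpec("1", 30.0, 0.9, (1, 1, 1)),
        QTLSpec("2", 70.0, 0.6, (1, 1, 0)),
    ],
    resid_sd=0.9,
    seed=19,
)
observed, plots, truth = simulate_dataset(config)
adjusted = adjust_for_environment(plots, config.trait)
ivgen = impute_interval_genotypes(observed, IntervalGrid.from_map(truth["map"]))

result = crossvalidate(
    adjusted, ivgen, k=6, seed=5,
    chain=ChainConfig(iterations=1500, burn_in=400, thin=5, seed=23),
)
print(result.as_frame("trait").round(3).to_string())
# fold correlations near 0.9: the adjusted values also separate the family
# means, which the family intercepts predict on top of the QTL term
print(f"\nmean predictive correlation: {result.mean_r:.3f} "
      f"(sd {result.sd_r:.3f} over {len(result.fold_r)} folds)")
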