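# Example configuration for the `mfqtl` command-line pipeline.
# Run the whole chain with:   mfqtl all examples/pipeline.yaml
# or stage by stage:          mfqtl simulate examples/pipeline.yaml; mfqtl prep ...
seed: 20240101
trait: FlYd
outdir: mfqtl_out

simulate:
  n_families: 3
  lines_per_family: 96
  chromosomes: [["1", 100.0], ["2", 100.0], ["3", 100.0]]
  marker_spacing_cm: 5.0
  qtls:
    - {chromosome: "2", position_cm: 50.0, effect: 1.0, segregating: [1, 1, 1]}
    - {chromosome: "3", position_cm: 25.0, effect: -0.6, segregating: [1, 0, 1]}
  resid_sd: 0.7
  missing_rate: 0.05
  family_means: [65.0, 67.5, 66.5]
  env_effects: {"2011": 1.2, "2012": -0.8, "2013": 0.3, "2014": -0.7}

chain: {iterations: 4000, burn_in: 1000, thin: 5}
permute: {n_perm: 20, level: 0.10, shorten: 0.25}
cv: {k: 6}
ideotype: {n_ideotypes: 3, genotypes_per_ideotype: 200}
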