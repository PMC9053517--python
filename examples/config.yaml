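# Example pipeline configuration: simulate a cohort with one injected
# cognitive-domain effect and run every stage.
#
#   pdprog run-all --config examples/config.yaml
#
# To analyze real data instead, replace the `simulation` block with:
#   inputs:
#     visits: path/to/visits.tsv
#     subjects: path/to/subjects.tsv
#     vcf: path/to/dosages.vcf          # or dosage_matrix + variant_table

output_dir: results/example_run
seed: 42

simulation:
  n_subjects: 300          # per cohort
  n_cohorts: 3
  n_variants: 200
  maf_range: [0.05, 0.5]
  causal_effects:
    - [0, cognitive, 0.4]  # variant index, domain, effect in slope-SD units

cap_months: 72
flip_direction: false
n_genetic_pcs: 5
maf_min: 0.01
sig_threshold: 5.0e-8
sex_stratified: false
stepwise: false
# certainty_threshold: 90
# trim_fraction: 0.05
# ledd_attenuation: 0.02
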