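# Example pipeline configuration for the smtgen CLI, at calibration scale.
#
#   smtgen make-reference examples/run.yaml
#   smtgen calibrate examples/run.yaml smtgen-output/reference.csv
#   smtgen generate examples/run.yaml smtgen-output/ensemble \
#       --reference smtgen-output/reference.csv
#
# Any field may be omitted to use the package default; --seed overrides
# master_seed. GA/AL sizes here are reduced so the whole pipeline finishes
# in a couple of minutes.

simulation:
  grid_width: 12
  grid_height: 12
  census: {macrophage: 8, neutrophil: 8, TH0: 6, TH1: 2, TH2: 2, precursor: 6}
  injury_size: 20
  duration: 89            # nine full day-bins at 10 steps/day
  sampling_interval: 1
  steps_per_day: 10.0

reference:
  subjects_per_cohort: {A: 20, B: 20}
  hidden_mrms_per_cohort: 1
  samples_per_subject: [3, 8]
  noise_sigma: 0.5
  injury_range: {A: [10, 22], B: [24, 40]}

ga:
  population_size: 12
  generations: 10
  elite_count: 2

al:
  batch_size: 30
  pool_size: 60
  rounds: 3

master_seed: 11
bin_width: 1.0
alpha: 1.5
per_member_replicates: 3
output_dir: smtgen-output
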