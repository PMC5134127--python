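# Default study cohort: 8 two-person households + 4 controls, five
# visits, two body sites, one household lost at month 6. Seed is usually
# overridden on the command line (`viroshare all --seed ...`).
schema_version: 1
seed: 1
simulate:
  n_households_two_person: 8
  n_controls: 4
  body_sites: [feces, saliva]
  n_core_viruses_per_subject: 18
  n_household_shared_viruses: 8
  n_background_pool: 300
  background_presence_prob: 0.06
  background_retention_prob: 0.45
  retention_prob: 0.85
  reacquisition_prob: 0.005
  transmission_rate: 7.0
  transmission_placebo_to_antibiotic_bias: 0.75
  mutation_rate: 0.002
  genome_length_range: [500, 1500]
  contigs_per_virus: 2
  missing_sample_prob: 0.02
  lost_households_month6: 1
permutation:
  n_iterations: 10000
  n_contigs_per_draw: 1000
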