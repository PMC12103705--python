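# End-to-end demo on two small synthetic cohorts (same effect preset,
# different noise seeds).  Runs in well under a minute on one CPU:
#
#   epiresponse all --config examples/demo_config.yaml --out demo_out
seed: 7
synthetic:
  preset: mid_dose
  n_genes: 240
  n_cohorts: 2
params:
  top_n: 60
  folds: 5
  families: [SVM, GB]
  subsets: [P, TSS, GB, All]
  transfer_family: SVM
  transfer_subset: All
transfer: true
discordant: true
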