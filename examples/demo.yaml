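# End-to-end synthetic demo: 2,000 patients, 50 diseases, 5 planted modules.
# Run with:  comorbinet run --config examples/demo.yaml
seed: 7
output_dir: demo_out

synthetic:
  kind: flat
  n_patients: 2000
  n_diseases: 50
  n_modules: 5
  mean_prevalence: 0.06
  prevalence_sigma: 0.4
  within_module_boost: 5.0
  n_visits_range: [2, 4]

thresholds:
  min_cooccurrence: 5
  min_rr: 1.0
  min_phi: 0.0

molecular:
  synthetic:
    n_genes: 600
    n_pathways: 30
    genes_per_disease_range: [6, 15]
    coupling: 0.7
    module_pool_size: 30

prediction:
  target: A000
  n_positive: 150
  n_negative: 150
  n_folds: 10
  models: [lr, svm, rf, nn]
  top_k: 10
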