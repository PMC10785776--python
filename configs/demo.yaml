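# Demo pipeline configuration: small enough to run in seconds.
# `pulsechase run-all --config configs/demo.yaml --out results/demo`
seed: 0
out_dir: results/demo
turnover_sim:
  n_proteins: 120
  peptides_per_protein: [3, 8]
  chase_times: [0.0, 1.0, 5.0, 21.0]
  label_efficiency: 0.9
  noise_cv: 0.2
  frac_slowed: 0.2
  rate_factor: 0.5
ip_sim:
  n_true_interactors: 60
  n_background: 40
  n_replicates: 3
bin_width: 5.0
labeling_threshold: 80.0
ratio_threshold: 3.0
alpha: 0.05
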