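# Full-pipeline run configuration (txfeedback pipeline run --config configs/pipeline.yaml)
outdir: scratch/pipeline_run
seed: 17

stages:
  simulate: true
  preprocess: true
  factorize: true
  enrich: true
  signature: true
  survey: true

# synthetic-cohort overrides (defaults emulate the full study design)
sim: {}

floor_fraction: 0.05        # Sigma floored at 5% of |D|
logfc_min: 0.5              # min max-pairwise log2 fold change to keep a gene
k: null                     # null => scan k_range by pattern robustness
k_range: [2, 6]
n_runs: 3                   # bootstrap refits per candidate k
robustness_threshold: 0.9
n_draws: 50                 # bootstrap draws behind the z-scores
n_perm: 10000               # permutations for the gene-set statistic

clustering:
  method: average
  metric: euclidean

survey_n_samples: 200
survey_tumor_types: [TYPE_A, TYPE_B]
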