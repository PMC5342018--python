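#!/usr/bin/env python
"""Generate the synthetic inhibitor-response cohort with planted ground truth.

Emulates the study design: 4 genetic backgrounds (Mock, EGFR, HRAS, PIK3CA)
x 4 treatments (control + 3 EGFR inhibitors) in triplicate, 500 genes with
two probes each, three planted expression programs (constant baseline,
oncogene-driven/treatment-repressed, feedback/treatment-induced), TF target
sets, and a colony-survival phenotype anti-correlated with feedback
induction.

Large raw matrices go to scratch/analysis/ (regenerable from the seed);
small ground-truth tables go to results/.
"""

import argparse
from pathlib import Path

from txfeedback import SimConfig, generate_truth, simulate_expression
from txfeedback import io

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=17)
args = ap.parse_args()

scratch = Path("scratch/analysis/data")
results = Path("results")
cfg = SimConfig(seed=args.seed)
truth = generate_truth(cfg)
bundle = simulate_expression(truth, cfg)

io.write_bundle(bundle, scratch)
io.write_gmt(truth.tf_targets, scratch / "tf_targets.gmt")
io.write_survival(truth.survival_true, results / "survival_true.tsv")
truth.P_true.rename_axis("pattern").to_csv(results / "P_true.tsv", sep="\t")
io.write_json({"reference": truth.signature_truth["reference"],
               "up": truth.signature_truth["up"],
               "down": truth.signature_truth["down"]},
              results / "signature_truth.json")

print(f"cohort: {bundle.values.shape[0]} probes x {bundle.values.shape[1]} samples "
      f"({len(cfg.backgrounds)} backgrounds x {len(cfg.treatments)} treatments "
      f"x {cfg.n_replicates} replicates), seed {args.seed}")
print(f"planted: 3 programs, {len(truth.tf_targets)} TF target sets, "
      f"reference gene {truth.signature_truth['reference']} "
      f"({len(truth.signature_truth['up'])} up / {len(truth.signature_truth['down'])} down)")
print(f"raw matrices -> {scratch}; ground truth -> {results}")
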