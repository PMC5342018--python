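#!/usr/bin/env python
"""Associate TF target sets with the inferred patterns and the reference gene.

Scores every TF target set against every pattern with the permutation
gene-set statistic on the amplitude z-scores, then runs the reference-gene
correlation + Wilcoxon TF-association procedure (the route that flags the
feedback regulator).
"""

import argparse
from pathlib import Path

import pandas as pd

from txfeedback import (gene_correlation_profile, gene_set_statistic,
                        resolve_gene_sets, tf_association)
from txfeedback import io

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=31)
ap.add_argument("--nperm", type=int, default=10_000)
args = ap.parse_args()

scratch = Path("scratch/analysis")
results = Path("results")
Z = pd.read_csv(results / "zscores.tsv", sep="\t", index_col=0)
sets = resolve_gene_sets(io.read_gmt(scratch / "data/tf_targets.gmt"), Z.index)
reference = io.read_signature(results / "signature_truth.json").reference_gene

rows = []
for i, (tf, members) in enumerate(sorted(sets.items())):
    for pattern in Z.columns:
        r = gene_set_statistic(Z, members, pattern, n_perm=args.nperm,
                               seed=args.seed + i)
        rows.append({"tf": tf, "pattern": pattern, "mean_z": r.statistic,
                     "p_value": r.p_value})
set_table = pd.DataFrame(rows)
set_table.to_csv(results / "tf_set_enrichment.tsv", sep="\t", index=False)
print("TF set vs pattern (permutation p):")
print(set_table.pivot(index="tf", columns="pattern", values="p_value").round(4))

full_sets = resolve_gene_sets(io.read_gmt(scratch / "data/tf_targets.gmt"),
                              set(Z.index) | {reference})
assoc = tf_association(gene_correlation_profile(Z, reference), full_sets, reference)
assoc.to_csv(results / "tf_association.tsv", sep="\t", index=False)
print(f"\nTF association for reference gene {reference} "
      f"(TFs annotating it, Wilcoxon one-sided):")
print(assoc.to_string(index=False))
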