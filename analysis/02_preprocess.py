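#!/usr/bin/env python
"""Collapse probes to genes and build the factorization input (D, Sigma).

Reads the raw cohort written by 01_simulate_cohort.py, picks one probe per
gene by the between-condition / within-replicate MAD ratio, forms condition
means and replicate standard deviations, floors Sigma at 5% of signal, and
keeps TF-annotated genes with a log2 fold change of at least 0.5 between
some pair of conditions.
"""

from pathlib import Path

from txfeedback import (apply_uncertainty_floor, collapse_probes,
                        condition_stats, filter_genes)
from txfeedback import io

scratch = Path("scratch/analysis")
bundle = io.read_bundle(scratch / "data/expression.tsv",
                        scratch / "data/expression_samples.tsv",
                        scratch / "data/expression_probes.tsv")
gene_sets = io.read_gmt(scratch / "data/tf_targets.gmt")

collapsed = collapse_probes(bundle)
fi = condition_stats(collapsed)
fi = apply_uncertainty_floor(fi, fraction=0.05)
fi = filter_genes(fi, gene_sets, logfc_min=0.5)

io.write_factor_input(fi, scratch / "factor_input")
io.write_bundle(collapsed, scratch / "collapsed", prefix="genes")

rep = fi.meta["filter_report"]
print(f"collapsed {bundle.values.shape[0]} probes -> {collapsed.values.shape[0]} genes")
print(f"filter: {rep['n_input']} genes in, {rep['removed_not_in_set']} not in any "
      f"TF set, {rep['removed_low_logfc']} below logFC 0.5, {rep['n_retained']} kept")
print(f"factor input -> {scratch/'factor_input'}")
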