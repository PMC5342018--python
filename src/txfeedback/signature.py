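"""Up/down feedback signature: construction, evaluation and stratification.

Treatment-induced expression changes (treated minus control means, log2
scale) are computed per background x drug contrast.  A reference gene's
target set is split into "up" and "down" members by two-way hierarchical
clustering of their change profiles; the cluster containing the reference
gene is "up".  The signature is evaluated in an independent change matrix by
ranking genes by the correlation of their change profile with the reference
gene's and testing the "up" set with a one-sided Wilcoxon rank-sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .enrich import EnrichmentResult, pearson_test, wilcoxon_rank_sum
from .errors import InputError, TxFeedbackError
from .factorization import FactorizationResult
from .preprocess import ExpressionBundle, condition_label

logger = logging.getLogger(__name__)


@dataclass
class Signature:
    """Reference gene with disjoint up- and down-regulated target sets."""

    reference_gene: str
    up: set[str]
    down: set[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise InputError("up and down sets must be disjoint")
        if self.reference_gene not in self.up:
            raise InputError("reference gene must belong to the up set")


def treatment_changes(expr: ExpressionBundle, control_treatment: str = "control",
                      ) -> pd.DataFrame:
    """Per-gene mean expression change, one contrast per background x drug.

    Contrast columns are labeled ``background|drug``.  A contrast missing
    either arm is skipped with a warning.
    """
    if not expr.is_gene_level:
        raise InputError("treatment_changes expects a gene-level bundle")
    meta = expr.sample_meta
    changes = {}
    for bg in meta["background"].unique():
        ctrl_cols = meta.index[(meta["background"] == bg)
                               & (meta["treatment"] == control_treatment)]
        for drug in meta.loc[meta["background"] == bg, "treatment"].unique():
            if drug == control_treatment:
                continue
            trt_cols = meta.index[(meta["background"] == bg) & (meta["treatment"] == drug)]
            if len(ctrl_cols) == 0 or len(trt_cols) == 0:
                logger.warning("contrast %s|%s missing an arm; skipped", bg, drug)
                continue
            changes[condition_label(bg, drug)] = (
                expr.values[trt_cols].mean(axis=1) - expr.values[ctrl_cols].mean(axis=1))
    return pd.DataFrame(changes)


def build_signature(changes: pd.DataFrame, targets, reference_gene: str,
                    method: str = "average", metric: str = "euclidean") -> Signature:
    """Split a target set into up/down by clustering change profiles.

    Agglomerative clustering (``method`` linkage, ``metric`` distance) of the
    target genes' rows, cut at two clusters; the cluster holding
    ``reference_gene`` becomes the up set.  Euclidean distance is the
    default: the up/down division is carried by the sign and magnitude of
    the changes, which correlation distance would remove; pass
    ``metric="correlation"`` to cluster on profile shape instead.
    """
    targets = [g for g in targets if g in changes.index]
    if reference_gene not in targets:
        raise InputError("reference gene must be among the (resolvable) targets")
    if len(targets) < 2:
        raise InputError("need at least 2 target genes to cluster")
    X = changes.loc[targets].to_numpy(dtype=float)
    dists = pdist(X, metric=metric)
    if not np.isfinite(dists).all():
        raise InputError("undefined pairwise distances (constant change profile?)")
    if np.allclose(dists, 0):
        raise TxFeedbackError("degenerate clustering: all change profiles identical")
    labels = fcluster(linkage(dists, method=method), t=2, criterion="maxclust")
    ref_label = labels[targets.index(reference_gene)]
    up = {g for g, lab in zip(targets, labels) if lab == ref_label}
    down = set(targets) - up
    return Signature(reference_gene=reference_gene, up=up, down=down)


def signature_enrichment(changes: pd.DataFrame, sig: Signature,
                         include_reference: bool = False,
                         ) -> tuple[EnrichmentResult, pd.DataFrame]:
    """Rank genes by correlation with the reference change profile; test the up set.

    Per-gene statistic: Pearson r across contrasts between the gene's change
    profile and the reference gene's.  The reference itself is excluded from
    both the up set and the background unless ``include_reference`` is set.
    One-sided (greater) Wilcoxon rank-sum of up-gene statistics against all
    remaining genes.
    """
    if changes.shape[1] < 3:
        raise InputError("need at least 3 contrasts to correlate change profiles")
    if sig.reference_gene not in changes.index:
        raise InputError("reference gene absent from the change matrix")
    ref = changes.loc[sig.reference_gene].to_numpy(dtype=float)
    pool = changes.drop(index=sig.reference_gene) if not include_reference else changes
    stats_rows = []
    for gene, row in pool.iterrows():
        vals = row.to_numpy(dtype=float)
        if np.std(vals) == 0 or np.std(ref) == 0:
            stats_rows.append((gene, np.nan))
            continue
        r, _ = pearson_test(vals, ref, alternative="two-sided")
        stats_rows.append((gene, r))
    table = pd.DataFrame(stats_rows, columns=["gene", "r_with_reference"]).set_index("gene")
    table["in_up_set"] = table.index.isin(sig.up - {sig.reference_gene}
                                          if not include_reference else sig.up)
    usable = table.dropna(subset=["r_with_reference"])
    x = usable.loc[usable["in_up_set"], "r_with_reference"].to_numpy()
    y = usable.loc[~usable["in_up_set"], "r_with_reference"].to_numpy()
    if x.size == 0 or y.size == 0:
        raise InputError("up set or background empty after exclusions")
    u, p = wilcoxon_rank_sum(x, y, alternative="greater")
    table = table.sort_values("r_with_reference", ascending=False, kind="mergesort")
    return (EnrichmentResult(statistic=float(u), p_value=float(p), direction="greater"),
            table)


def pattern_delta_survival(result: FactorizationResult | pd.DataFrame,
                           survival: pd.Series, pattern,
                           control_treatment: str = "control",
                           alternative: str = "two-sided") -> tuple[float, float]:
    """Correlate a pattern's treatment deltas with relative survival.

    ``survival`` is indexed by (background, drug).  For each entry the delta
    is the pattern's value in the treated condition minus its value in the
    same background's control condition; the function returns the Pearson r
    and p-value between deltas and survival.
    """
    P = result.P if isinstance(result, FactorizationResult) else result
    row = P.loc[pattern] if pattern in P.index else P.iloc[int(pattern)]
    deltas = []
    for bg, drug in survival.index:
        ctrl = condition_label(bg, control_treatment)
        trt = condition_label(bg, drug)
        if ctrl not in row.index:
            raise InputError(f"missing control condition {ctrl!r}")
        if trt not in row.index:
            raise InputError(f"missing treated condition {trt!r}")
        deltas.append(row[trt] - row[ctrl])
    return pearson_test(np.asarray(deltas), survival.to_numpy(dtype=float),
                        alternative=alternative)


def stratify_by_marker(expr: ExpressionBundle, marker_gene: str,
                       rule: str = "mean", threshold: float | None = None,
                       ) -> tuple[pd.Series, float]:
    """Label samples low/high by a marker gene's cohort-wide level.

    The threshold is the cohort mean (default) or median of the marker's
    expression over all samples, unless given explicitly.  Samples strictly
    below the threshold are "low"; all others (including exact ties) "high".
    """
    if marker_gene not in expr.values.index:
        raise InputError(f"marker gene {marker_gene!r} absent from the expression matrix")
    marker = expr.values.loc[marker_gene]
    if threshold is None:
        if rule == "mean":
            threshold = float(marker.mean())
        elif rule == "median":
            threshold = float(marker.median())
        else:
            raise InputError(f"unknown stratification rule {rule!r}")
    labels = pd.Series(np.where(marker < threshold, "low", "high"),
                       index=marker.index, name=f"{marker_gene}_level")
    return labels, float(threshold)
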