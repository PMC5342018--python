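"""Amplitude z-scores, gene-set statistics and TF-association tests.

Gene-level uncertainty from the factorization's bootstrap draws is summarized
as a z-score per gene and pattern (mean over draws divided by the draw SD).
Gene sets are scored against a pattern by the mean member z-score with a
permutation null over random same-size sets.  A reference gene is associated
with transcription factors by correlating z-score rows across patterns and
comparing target-gene correlations to the background with a one-sided
Wilcoxon rank-sum test, BH-corrected across TFs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .factorization import FactorizationResult

logger = logging.getLogger(__name__)

#: Floor applied to the draw standard deviation before forming z-scores.
ZSCORE_SD_FLOOR = 1e-12
#: Exact Wilcoxon enumeration is used up to this combined sample size.
EXACT_WILCOXON_MAX_N = 12


@dataclass
class EnrichmentResult:
    statistic: float
    p_value: float
    n_permutations: int | None = None   # None => exact / analytic
    direction: str = "greater"
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise InputError(f"p-value outside [0, 1]: {self.p_value}")


def resolve_gene_sets(gene_sets: dict[str, set[str]], universe) -> dict[str, set[str]]:
    """Intersect each set with the expression universe, dropping empties."""
    universe = set(universe)
    resolved = {}
    for name, members in gene_sets.items():
        kept = set(members) & universe
        dropped = len(members) - len(kept)
        if dropped:
            logger.warning("gene set %s: %d unresolvable labels dropped", name, dropped)
        if kept:
            resolved[name] = kept
        else:
            logger.warning("gene set %s empty after resolution; dropped", name)
    return resolved


def compute_zscores(result: FactorizationResult) -> pd.DataFrame:
    """Per-entry z-score of A over bootstrap draws: mean / SD (SD floored).

    Entries whose draws are all zero get z = 0; constant nonzero draws hit
    the SD floor and come out large but finite.
    """
    if len(result.samples) < 2:
        raise InputError("need at least 2 draws to form z-scores")
    draws = np.stack([a for a, _ in result.samples])  # draws x genes x k
    mean = draws.mean(axis=0)
    sd = draws.std(axis=0, ddof=1)
    z = mean / np.maximum(sd, ZSCORE_SD_FLOOR)
    z[mean == 0] = 0.0
    return pd.DataFrame(z, index=result.A.index, columns=result.A.columns)


def gene_set_statistic(Z: pd.DataFrame, gene_set, pattern, n_perm: int = 10_000,
                       seed: int = 0) -> EnrichmentResult:
    """Mean member z-score in one pattern, with a permutation p-value.

    The null draws ``n_perm`` random gene sets of the same size from the
    universe; the one-sided (greater) p-value uses the add-one correction
    ``(1 + #{perm >= obs}) / (1 + n_perm)``.
    """
    col = Z[pattern] if pattern in Z.columns else Z.iloc[:, int(pattern)]
    members = [g for g in gene_set if g in Z.index]
    if not members:
        raise InputError("gene set does not intersect the z-score universe")
    flags = ()
    if n_perm < 100:
        flags = ("few_permutations",)
        logger.warning("n_perm=%d is small; p-value resolution is coarse", n_perm)
    obs = float(col.loc[members].mean())
    rng = np.random.default_rng(seed)
    values = col.to_numpy()
    size = len(members)
    idx = np.empty((n_perm, size), dtype=int)
    for i in range(n_perm):
        idx[i] = rng.choice(len(values), size=size, replace=False)
    null = values[idx].mean(axis=1)
    # tolerance so exact ties (e.g. the set equals the universe) count as >=
    tol = 1e-10 * max(1.0, abs(obs))
    p = (1 + int(np.sum(null >= obs - tol))) / (1 + n_perm)
    return EnrichmentResult(statistic=obs, p_value=float(p),
                            n_permutations=n_perm, direction="greater", flags=flags)


def gene_correlation_profile(Z: pd.DataFrame, query_gene: str) -> pd.Series:
    """Pearson r of every other gene's z-score row with the query's, across patterns.

    With only k patterns the correlation rests on k points; k = 2 is allowed
    but degenerate (|r| = 1 whenever defined) and warned about.  Rows with
    zero variance yield NaN.
    """
    if query_gene not in Z.index:
        raise InputError(f"query gene {query_gene!r} not in the z-score universe")
    if Z.shape[1] < 2:
        raise InputError("need at least 2 patterns to correlate rows")
    if Z.shape[1] == 2:
        logger.warning("correlations over only 2 patterns are degenerate")
    q = Z.loc[query_gene].to_numpy(dtype=float)
    M = Z.drop(index=query_gene)
    X = M.to_numpy(dtype=float)
    qc = q - q.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    qn = np.linalg.norm(qc)
    Xn = np.linalg.norm(Xc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ qc) / (Xn * qn)
    r[(Xn == 0) | (qn == 0)] = np.nan
    return pd.Series(r, index=M.index, name=f"r_with_{query_gene}")


def tf_association(correlations: pd.Series, gene_sets: dict[str, set[str]],
                   query_gene: str) -> pd.DataFrame:
    """Wilcoxon TF association for a reference gene's correlation profile.

    Only TFs annotating the query gene as a target are tested.  For each, the
    remaining targets' correlation values are compared to all other genes
    with a one-sided (greater) rank-sum test.  Returns a table sorted by
    p-value with a BH-adjusted column; empty (with a warning) when no TF
    annotates the query.
    """
    candidates = {tf: members for tf, members in gene_sets.items() if query_gene in members}
    if not candidates:
        logger.warning("no TF annotates %s as a target", query_gene)
        return pd.DataFrame(columns=["tf", "statistic", "p_value", "p_adjusted", "n_targets"])
    corr = correlations.drop(index=query_gene, errors="ignore").dropna()
    rows = []
    for tf, members in sorted(candidates.items()):
        targets = corr.index.intersection(sorted((members - {query_gene})))
        if len(targets) == 0:
            logger.warning("TF %s has no remaining resolvable targets; skipped", tf)
            continue
        x = corr.loc[targets].to_numpy()
        y = corr.drop(index=targets).to_numpy()
        u, p = wilcoxon_rank_sum(x, y, alternative="greater")
        rows.append({"tf": tf, "statistic": u, "p_value": p, "n_targets": len(targets)})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
        table = table.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    return table


def wilcoxon_rank_sum(x, y, alternative: str = "greater") -> tuple[float, float]:
    """Mann-Whitney U (for x) with exact small-sample p by enumeration.

    The exact path enumerates all assignments when ``len(x) + len(y)`` is at
    most 12 and the data carry no ties; otherwise the normal approximation
    with midranks, tie-corrected variance and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be non-empty")
    if alternative not in ("greater", "less", "two-sided"):
        raise InputError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    if x.size + y.size <= EXACT_WILCOXON_MAX_N and no_ties:
        return _exact_rank_sum(x, y, alternative)
    res = stats.mannwhitneyu(x, y, alternative=alternative,
                             method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _exact_rank_sum(x: np.ndarray, y: np.ndarray, alternative: str) -> tuple[float, float]:
    pooled = np.concatenate([x, y])
    n, m = x.size, y.size
    u_obs = float(np.sum(x[:, None] > y[None, :]))
    us = np.array([
        np.sum(pooled[list(combo)][:, None] > np.delete(pooled, list(combo))[None, :])
        for combo in itertools.combinations(range(n + m), n)
    ], dtype=float)
    total = len(us)
    if alternative == "greater":
        p = np.sum(us >= u_obs) / total
    elif alternative == "less":
        p = np.sum(us <= u_obs) / total
    else:
        mu = n * m / 2.0
        p = min(1.0, np.sum(np.abs(us - mu) >= abs(u_obs - mu)) / total)
    return u_obs, float(p)


def pearson_test(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Pearson correlation with the t-distributed test (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InputError("need equal-length samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InputError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
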