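"""Probe-to-gene collapse, condition statistics, uncertainty flooring and gene filtering.

Expression values are log2-scale intensities.  Samples belong to experimental
conditions defined by a genetic background crossed with a drug treatment, each
measured in replicate.  The factorization stage consumes a condition-mean
matrix ``D`` together with an elementwise uncertainty matrix ``Sigma`` derived
from replicate variability with a proportional floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, NoGenesPassFilterError

logger = logging.getLogger(__name__)

#: Separator joining background and treatment into a condition label.
CONDITION_SEP = "|"


def condition_label(background: str, treatment: str) -> str:
    return f"{background}{CONDITION_SEP}{treatment}"


@dataclass
class ExpressionBundle:
    """Log-scale expression values plus per-sample metadata.

    Parameters
    ----------
    values
        Probe- or gene-level matrix, rows indexed by probe/gene identifiers,
        columns by sample identifiers.
    sample_meta
        One row per sample (index = sample id) with columns ``background``,
        ``treatment`` and ``replicate``.
    probe_map
        Mapping probe id -> gene id; ``None`` for gene-level bundles.
    provenance
        For collapsed bundles, the probe chosen to represent each gene.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    probe_map: pd.Series | None = None
    provenance: pd.Series | None = None

    def __post_init__(self) -> None:
        required = {"background", "treatment", "replicate"}
        missing = required - set(self.sample_meta.columns)
        if missing:
            raise InputError(f"sample_meta missing columns: {sorted(missing)}")
        if list(self.values.columns) != list(self.sample_meta.index):
            raise InputError("values columns and sample_meta index disagree")
        if self.sample_meta[["background", "treatment", "replicate"]].isna().any().any():
            raise InputError("sample_meta contains missing labels")
        if self.probe_map is not None:
            unmapped = self.values.index.difference(self.probe_map.index)
            if len(unmapped):
                raise InputError(f"{len(unmapped)} probes missing from probe_map")

    @property
    def is_gene_level(self) -> bool:
        return self.probe_map is None

    def condition_of(self) -> pd.Series:
        """Condition label (background|treatment) per sample."""
        meta = self.sample_meta
        return meta["background"].astype(str) + CONDITION_SEP + meta["treatment"].astype(str)


@dataclass
class FactorInput:
    """Condition-mean matrix D with elementwise uncertainties Sigma.

    ``D`` and ``Sigma`` share row (gene) and column (condition) labels;
    ``condition_meta`` records the background and treatment of each column.
    ``meta`` carries processing flags (single-replicate conditions, filter
    report, floor parameters).
    """

    D: pd.DataFrame
    Sigma: pd.DataFrame
    condition_meta: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.D.shape != self.Sigma.shape:
            raise InputError("D and Sigma shapes differ")
        if not (self.D.index.equals(self.Sigma.index) and self.D.columns.equals(self.Sigma.columns)):
            raise InputError("D and Sigma labels differ")
        if list(self.condition_meta.index) != list(self.D.columns):
            raise InputError("condition_meta index does not match D columns")


def _mad(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Raw median absolute deviation (no consistency constant)."""
    med = np.median(values, axis=axis, keepdims=True)
    return np.median(np.abs(values - med), axis=axis)


def collapse_probes(bundle: ExpressionBundle) -> ExpressionBundle:
    """Pick one probe per gene by the ratio of between-condition to within-replicate MAD.

    For each probe the score is ``MAD(condition means) / median over conditions
    of the within-condition replicate MAD``.  A zero denominator with a
    positive numerator scores ``+inf``; 0/0 scores 0.  Ties break toward the
    lexicographically smallest probe identifier.
    """
    if bundle.probe_map is None:
        raise InputError("collapse_probes requires a probe_map")
    conditions = bundle.condition_of()
    if conditions.nunique() < 2:
        raise InputError("need at least 2 conditions to score probes")

    # Probe x condition matrices of replicate means and within-replicate MADs.
    groups = bundle.values.T.groupby(conditions)
    cond_means = groups.mean().T  # probes x conditions
    within = groups.apply(lambda df: pd.Series(_mad(df.to_numpy(), axis=0), index=df.columns)).T

    numer = _mad(cond_means.to_numpy(), axis=1)
    denom = np.median(within.to_numpy(), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0),
                         np.where(numer > 0, np.inf, 0.0))
    scores = pd.DataFrame({"gene": bundle.probe_map.loc[bundle.values.index].to_numpy(),
                           "score": score}, index=bundle.values.index)
    # Highest score wins; exact ties resolve to the smallest probe id.
    best = scores.groupby("gene")["score"].transform("max")
    tied = scores[scores["score"] == best]
    chosen = (tied.rename_axis("probe").reset_index()
              .sort_values(["gene", "probe"], kind="mergesort")
              .groupby("gene", sort=True).head(1).set_index("probe"))

    values = bundle.values.loc[chosen.index]
    values.index = chosen["gene"].to_numpy()
    provenance = pd.Series(chosen.index.to_numpy(), index=chosen["gene"].to_numpy(), name="probe")
    return ExpressionBundle(values=values, sample_meta=bundle.sample_meta.copy(),
                            probe_map=None, provenance=provenance)


def condition_stats(bundle: ExpressionBundle) -> FactorInput:
    """Per-condition replicate mean (D) and sample standard deviation (Sigma).

    Conditions with a single replicate get an undefined (NaN) Sigma entry and
    are flagged in ``meta['single_replicate_conditions']``; the caller must
    apply :func:`apply_uncertainty_floor` before factorization.
    """
    conditions = bundle.condition_of()
    groups = bundle.values.T.groupby(conditions)
    D = groups.mean().T
    Sigma = groups.std(ddof=1).T  # NaN where a condition has one replicate
    counts = groups.size()
    singles = counts[counts < 2].index.tolist()
    if singles:
        logger.warning("conditions with a single replicate (Sigma undefined): %s", singles)

    meta_rows = []
    for cond in D.columns:
        bg, tr = cond.split(CONDITION_SEP, 1)
        meta_rows.append({"condition": cond, "background": bg, "treatment": tr,
                          "n_replicates": int(counts[cond])})
    condition_meta = pd.DataFrame(meta_rows).set_index("condition")
    return FactorInput(D=D, Sigma=Sigma, condition_meta=condition_meta,
                       meta={"single_replicate_conditions": singles})


def apply_uncertainty_floor(fi: FactorInput, fraction: float = 0.05,
                            eps: float = 1e-6) -> FactorInput:
    """Floor Sigma at ``fraction * |D|`` elementwise.

    Entries where ``D == 0`` (where the proportional floor vanishes) are
    floored at ``eps`` instead, so Sigma is strictly positive everywhere.
    Undefined (NaN) Sigma entries are replaced by the floor itself.
    """
    if fraction <= 0:
        raise InputError(f"floor fraction must be > 0, got {fraction}")
    floor = fraction * np.abs(fi.D.to_numpy())
    floor = np.where(floor > 0, floor, eps)
    sigma = np.fmax(fi.Sigma.to_numpy(), floor)  # fmax: NaN entries -> floor
    Sigma = pd.DataFrame(sigma, index=fi.Sigma.index, columns=fi.Sigma.columns)
    meta = dict(fi.meta, floor_fraction=fraction, floor_eps=eps)
    return FactorInput(D=fi.D.copy(), Sigma=Sigma, condition_meta=fi.condition_meta.copy(),
                       meta=meta)


def filter_genes(fi: FactorInput, gene_sets: dict[str, set[str]],
                 logfc_min: float = 0.5) -> FactorInput:
    """Keep genes annotated in at least one TF target set with a large enough response.

    A gene is retained when (a) it belongs to the union of the supplied target
    sets and (b) the largest difference of its condition means (log2 fold
    change between some pair of conditions) is at least ``logfc_min``.  Counts
    removed by each criterion land in ``meta['filter_report']``.
    """
    universe = set().union(*gene_sets.values()) if gene_sets else set()
    in_set = fi.D.index.to_series().isin(universe)
    rng = fi.D.max(axis=1) - fi.D.min(axis=1)  # max pairwise |difference|
    responsive = rng >= logfc_min
    keep = in_set & responsive
    report = {
        "n_input": int(len(fi.D)),
        "removed_not_in_set": int((~in_set).sum()),
        "removed_low_logfc": int((in_set & ~responsive).sum()),
        "n_retained": int(keep.sum()),
    }
    logger.info("gene filter: %s", report)
    if report["n_retained"] == 0:
        raise NoGenesPassFilterError("no genes pass the TF-membership + logFC filter")
    meta = dict(fi.meta, filter_report=report)
    return FactorInput(D=fi.D.loc[keep].copy(), Sigma=fi.Sigma.loc[keep].copy(),
                       condition_meta=fi.condition_meta.copy(), meta=meta)
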