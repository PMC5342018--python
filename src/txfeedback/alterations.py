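"""Somatic alteration survey over a signaling-network node list.

A sample counts as altered in a gene when it carries a mutation, a GISTIC
copy-number score of +2 (amplification) or -2 (homozygous deletion); shallow
gains and losses (+/-1) do not count.  Genes collapse onto network nodes
(families) by boolean OR — e.g. a RAS node altered when any of HRAS, KRAS or
NRAS is.  Frequencies are reported per node and tumor type, plus a cross-type
summary (unweighted mean of per-type percentages, with the pooled frequency
alongside).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

GISTIC_LEVELS = {-2, -1, 0, 1, 2}

ALTERATION_COLUMNS = ["sample_id", "tumor_type", "gene", "mutated", "gistic"]


def validate_alteration_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(ALTERATION_COLUMNS) - set(table.columns)
    if missing:
        raise InputError(f"alteration table missing columns: {sorted(missing)}")
    bad = set(table["gistic"].unique()) - GISTIC_LEVELS
    if bad:
        raise InputError(f"GISTIC scores outside {{-2..2}}: {sorted(bad)}")
    dup = table.duplicated(subset=["sample_id", "tumor_type", "gene"])
    if dup.any():
        raise InputError("duplicate (sample, tumor_type, gene) rows")
    return table


def is_altered(mutated: bool, gistic: int) -> bool:
    """Alteration rule: mutation, amplification (+2) or homozygous deletion (-2)."""
    if gistic not in GISTIC_LEVELS:
        raise InputError(f"GISTIC score {gistic} outside {{-2,-1,0,1,2}}")
    return bool(mutated) or gistic == 2 or gistic == -2


def _altered_wide(table: pd.DataFrame) -> pd.DataFrame:
    """(sample, tumor_type) x gene boolean alteration matrix.

    Missing gene entries for a sample are treated as unaltered (GISTIC 0);
    the number of imputed cells is logged.
    """
    validate_alteration_table(table)
    flags = table.assign(
        altered=table["mutated"].astype(bool)
        | table["gistic"].isin([-2, 2]))
    wide = flags.pivot_table(index=["sample_id", "tumor_type"], columns="gene",
                             values="altered", aggfunc="any")
    n_missing = int(wide.isna().sum().sum())
    if n_missing:
        logger.info("imputed %d missing sample-gene entries as unaltered", n_missing)
    return wide.fillna(False).astype(bool)


def collapse_families(table: pd.DataFrame, families: dict[str, list[str]]) -> pd.DataFrame:
    """Node-level boolean alteration matrix: OR over each family's member genes.

    Returns a (sample, tumor_type)-indexed frame with one boolean column per
    node.  Members absent from the table are skipped with a warning; a node
    with no present member is dropped.
    """
    wide = _altered_wide(table)
    out = {}
    for node, members in families.items():
        if not members:
            raise InputError(f"family {node!r} has an empty member list")
        present = [g for g in members if g in wide.columns]
        absent = sorted(set(members) - set(present))
        if absent:
            logger.warning("node %s: members missing from table, skipped: %s", node, absent)
        if not present:
            logger.warning("node %s dropped: no member present in the table", node)
            continue
        out[node] = wide[present].any(axis=1)
    return pd.DataFrame(out, index=wide.index)


def alteration_frequency(node_table: pd.DataFrame) -> pd.DataFrame:
    """Percent altered samples per node (columns) and tumor type (rows)."""
    if node_table.empty:
        raise InputError("empty node-level table")
    types = node_table.index.get_level_values("tumor_type")
    grouped = node_table.groupby(types)
    counts = grouped.size()
    if (counts == 0).any():
        raise InputError("tumor type with zero samples")
    return grouped.mean() * 100.0


def average_across_types(freqs: pd.DataFrame) -> pd.Series:
    """Unweighted mean of per-tumor-type percentages, per node."""
    if freqs.empty:
        raise InputError("no tumor types to average over")
    return freqs.mean(axis=0).rename("mean_pct_across_types")


def pooled_frequency(node_table: pd.DataFrame) -> pd.Series:
    """Percent altered over all samples pooled, ignoring tumor type."""
    if node_table.empty:
        raise InputError("empty node-level table")
    return (node_table.mean(axis=0) * 100.0).rename("pooled_pct")
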