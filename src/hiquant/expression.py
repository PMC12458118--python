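"""Relative qPCR quantification by the ΔΔCt method.

For each sample, the target gene's Ct is normalized to a housekeeping
gene (ΔCt = Ct_target − Ct_housekeeping); ΔΔCt subtracts the mean ΔCt of
a reference group, and expression is reported as the fold change
2^(−ΔΔCt).  Technical replicates are averaged on the Ct scale before
any subtraction, and group summaries use geometric means because folds
live on a log scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CtRecord", "FoldChange", "delta_delta_ct", "fold_table", "group_geometric_means"]

logger = logging.getLogger(__name__)


@dataclass
class CtRecord:
    """One qPCR measurement: threshold cycle of one gene in one sample."""

    sample_id: str
    group: str
    gene: str
    ct: float
    hemisphere: str = ""


@dataclass
class FoldChange:
    """2^(−ΔΔCt) fold change of one sample relative to the reference group."""

    sample_id: str
    group: str
    gene: str
    fold: float
    reference_group: str


def delta_delta_ct(
    records: list[CtRecord] | pd.DataFrame,
    target_gene: str,
    housekeeping_gene: str,
    reference_group: str,
) -> list[FoldChange]:
    """Per-sample fold changes of ``target_gene`` by the ΔΔCt method.

    Parameters
    ----------
    records : list of CtRecord or DataFrame
        Needs columns/fields sample_id, group, gene, ct.  Technical
        replicates (repeated (sample, gene) rows) are averaged on the Ct
        scale.
    target_gene, housekeeping_gene : str
    reference_group : str
        Group whose mean ΔCt anchors ΔΔCt; its folds have geometric
        mean 1 by construction.

    Returns
    -------
    list of FoldChange
        Samples missing a housekeeping (or target) Ct are skipped with a
        logged diagnostic; an empty reference group is an error.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([vars(r) for r in records])
    required = {"sample_id", "group", "gene", "ct"}
    if not required <= set(df.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    df = df[df["gene"].isin([target_gene, housekeeping_gene])]
    # replicate averaging on the Ct scale
    ct = (
        df.groupby(["sample_id", "group", "gene"], sort=True)["ct"]
        .mean()
        .unstack("gene")
        .reset_index()
    )
    usable = ct.dropna(subset=[g for g in (target_gene, housekeeping_gene) if g in ct.columns])
    if target_gene not in ct.columns or housekeeping_gene not in ct.columns:
        raise ValueError("no Ct values found for the requested genes")
    skipped = set(ct["sample_id"]) - set(usable["sample_id"])
    for sid in sorted(skipped):
        logger.warning("sample %s skipped: missing %s or %s Ct", sid, target_gene, housekeeping_gene)
    usable = usable.assign(delta_ct=usable[target_gene] - usable[housekeeping_gene])
    ref = usable.loc[usable["group"] == reference_group, "delta_ct"]
    if ref.empty:
        raise ValueError(f"reference group {reference_group!r} has no usable samples")
    ddct = usable["delta_ct"] - ref.mean()
    folds = np.power(2.0, -ddct)
    return [
        FoldChange(
            sample_id=row.sample_id,
            group=row.group,
            gene=target_gene,
            fold=float(f),
            reference_group=reference_group,
        )
        for row, f in zip(usable.itertuples(), folds)
    ]


def fold_table(folds: list[FoldChange]) -> pd.DataFrame:
    """Fold changes as a tidy DataFrame."""
    return pd.DataFrame([vars(f) for f in folds])


def group_geometric_means(folds: list[FoldChange]) -> pd.Series:
    """Geometric mean fold per group (folds are log-scale quantities)."""
    df = fold_table(folds)
    return df.groupby("group")["fold"].apply(lambda x: float(np.exp(np.log(x).mean())))
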