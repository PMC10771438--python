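"""Knockdown-vs-control differential expression per time point.

For each day of the time course, log2 fold change is the difference of
replicate means on the log2 scale (knockdown minus control), tested per
gene with a two-tailed unpaired t-test and adjusted across all tested
genes by Benjamini-Hochberg.  A gene is called up- or down-regulated
when |log2FC| exceeds log2 of the fold-change threshold (FC > |2| means
|log2FC| > 1) and the adjusted P is below the FDR threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import ExpressionMatrix

__all__ = ["DEResult", "diff_expression", "top_changed"]

logger = logging.getLogger(__name__)


@dataclass
class DEResult:
    """Per-day differential-expression result.

    ``table``: gene_id, log2fc, p, fdr, call ('up' | 'down' | 'ns').
    """

    day: int
    table: pd.DataFrame
    up_set: set[str]
    down_set: set[str]
    fc_threshold: float
    q_threshold: float


def diff_expression(
    expr: ExpressionMatrix,
    day: int,
    fc_threshold: float = 2.0,
    q_threshold: float = 0.05,
    control: str = "control",
    treatment: str = "kd",
) -> DEResult:
    """Two-group DE at one day of the knockdown time course."""
    if fc_threshold <= 1.0:
        raise ValueError(f"fc_threshold must be > 1, got {fc_threshold}")
    if not 0.0 < q_threshold < 1.0:
        raise ValueError(f"q_threshold must be in (0, 1), got {q_threshold}")
    ann = expr.sample_annotations.loc[expr.sample_ids]
    sel = ann["day"] == day
    groups = {}
    for cond in (control, treatment):
        cols = ann.index[sel & (ann["condition"] == cond)]
        if len(cols) < 2:
            raise ValueError(
                f"condition {cond!r} has {len(cols)} sample(s) at day {day}; "
                "need >= 2 replicates"
            )
        groups[cond] = expr.values[cols].to_numpy()

    log2fc = groups[treatment].mean(axis=1) - groups[control].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(groups[treatment], groups[control], axis=1)
    p = np.where(np.isfinite(p), p, 1.0)  # zero-variance genes: no call
    fdr = multipletests(p, method="fdr_bh")[1]

    lfc_cut = np.log2(fc_threshold)
    up = (log2fc > lfc_cut) & (fdr < q_threshold)
    down = (log2fc < -lfc_cut) & (fdr < q_threshold)
    call = np.where(up, "up", np.where(down, "down", "ns"))
    table = pd.DataFrame(
        {
            "gene_id": expr.probe_ids,
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "call": call,
        }
    )
    up_set = set(table.loc[up, "gene_id"])
    down_set = set(table.loc[down, "gene_id"])
    logger.info(
        "diff_expression day %s: %d up, %d down of %d genes",
        day, len(up_set), len(down_set), len(table),
    )
    return DEResult(
        day=day,
        table=table,
        up_set=up_set,
        down_set=down_set,
        fc_threshold=fc_threshold,
        q_threshold=q_threshold,
    )


def top_changed(result: DEResult, k: int = 10) -> pd.DataFrame:
    """The k most up- and k most down-regulated significant genes.

    Ranked by signed log2 fold change (ties broken by gene id); if fewer
    than k genes are significant in a direction the full set is returned
    and ``attrs['truncated']`` is set.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    sig = result.table[result.table["call"] != "ns"]
    ups = sig[sig["call"] == "up"].sort_values(
        ["log2fc", "gene_id"], ascending=[False, True]
    )
    downs = sig[sig["call"] == "down"].sort_values(
        ["log2fc", "gene_id"], ascending=[True, True]
    )
    truncated = len(ups) < k or len(downs) < k
    out = pd.concat([ups.head(k), downs.head(k)], ignore_index=True)
    out.attrs["truncated"] = bool(truncated)
    if truncated:
        logger.warning(
            "top_changed: fewer than k=%d significant genes in a direction "
            "(%d up, %d down)", k, len(ups), len(downs),
        )
    return out
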