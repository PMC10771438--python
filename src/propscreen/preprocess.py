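"""Input preparation: qPCR relative quantification, replicate
aggregation, and the across-line ANOVA probe filter.

Relative expression follows the 2^-ddCt convention: target cycle
thresholds are normalized to a reference transcript (dCt = Ct_target -
Ct_reference) and expressed relative to the mean dCt of a calibrator
group, so the calibrator's geometric-mean relative expression is 1.

The probe filter keeps probes whose expression differs across cell lines
by a one-way ANOVA (optionally Benjamini-Hochberg adjusted), emulating
the upstream selection of line-variable probes that feeds the screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import ExpressionMatrix, MarkerPanel

__all__ = [
    "FilterCriteria",
    "relative_expression",
    "aggregate_replicates",
    "anova_filter",
]

logger = logging.getLogger(__name__)


@dataclass
class FilterCriteria:
    """Probe-filter settings: across-line one-way ANOVA at ``alpha`` with
    optional BH adjustment and an optional mean-expression floor."""

    test: str = "anova"
    alpha: float = 0.05
    adjust: str = "bh"  # "bh" | "none"
    min_mean_log2: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.test != "anova":
            raise ValueError(f"unsupported test: {self.test!r}")
        if self.adjust not in ("bh", "none"):
            raise ValueError(f"adjust must be 'bh' or 'none', got {self.adjust!r}")


def relative_expression(
    ct_target: pd.Series,
    ct_reference: pd.Series,
    sample_groups: pd.Series,
    calibrator: str,
) -> tuple[pd.Series, list[str]]:
    """2^-ddCt relative expression per sample.

    Parameters
    ----------
    ct_target, ct_reference
        Cycle thresholds per sample (matched index).
    sample_groups
        Group label per sample (e.g. cell line).
    calibrator
        Group whose mean dCt defines the baseline; its samples have
        geometric-mean relative expression 1.

    Returns
    -------
    (values, excluded)
        Relative expression for usable samples, and ids of samples
        excluded for a missing target or reference measurement (each
        logged as a warning).
    """
    ct_target = pd.Series(ct_target, dtype=float)
    ct_reference = ct_reference.reindex(ct_target.index).astype(float)
    sample_groups = sample_groups.reindex(ct_target.index)
    if calibrator not in set(sample_groups.dropna()):
        raise ValueError(f"calibrator group {calibrator!r} has no samples")

    usable = ct_target.notna() & ct_reference.notna()
    excluded = list(ct_target.index[~usable])
    for sid in excluded:
        logger.warning("sample %s excluded: missing Ct measurement", sid)

    d_ct = ct_target[usable] - ct_reference[usable]
    cal = d_ct[sample_groups[usable] == calibrator]
    dd_ct = d_ct - cal.mean()
    return np.exp2(-dd_ct), excluded


def aggregate_replicates(panel: MarkerPanel) -> pd.DataFrame:
    """Arithmetic replicate mean per (line, marker); the replicate count
    is recorded in ``DataFrame.attrs['n_replicates']``."""
    means = panel.line_marker_means()
    means.attrs["n_replicates"] = int(
        panel.data.groupby(["line", "marker"])["replicate"].count().iloc[0]
    )
    means.attrs["protocol"] = panel.protocol
    return means


def anova_filter(
    expr: ExpressionMatrix,
    criteria: FilterCriteria,
    condition: Optional[str] = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Keep probes that differ across lines by one-way ANOVA.

    Returns the filtered matrix and a per-probe report with columns
    ``F``, ``P``, ``P_adj`` and ``kept``.  Probes with zero variance
    (undefined F) are dropped and logged, not raised.
    """
    ann = expr.sample_annotations.loc[expr.sample_ids]
    if condition is not None:
        cols = ann.index[ann["condition"] == condition]
    else:
        cols = ann.index
    groups_lbl = ann.loc[cols, "line"]
    lines = groups_lbl.unique()
    if len(lines) < 2:
        raise ValueError("anova_filter needs >= 2 lines")
    group_arrays = [
        expr.values[groups_lbl.index[groups_lbl == ln]].to_numpy() for ln in lines
    ]
    if min(a.shape[1] for a in group_arrays) < 2:
        raise ValueError("anova_filter needs >= 2 replicates per line")

    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat, p_val = stats.f_oneway(*group_arrays, axis=1)

    degenerate = ~np.isfinite(p_val)
    n_degenerate = int(degenerate.sum())
    if n_degenerate:
        logger.warning(
            "%d probe(s) with undefined F (zero variance) dropped", n_degenerate
        )

    p_adj = np.full_like(p_val, np.nan)
    ok = ~degenerate
    if criteria.adjust == "bh":
        if ok.any():
            p_adj[ok] = multipletests(p_val[ok], method="fdr_bh")[1]
    else:
        p_adj[ok] = p_val[ok]

    kept = ok & (p_adj < criteria.alpha)
    if criteria.min_mean_log2 is not None:
        kept &= expr.values[cols].mean(axis=1).to_numpy() >= criteria.min_mean_log2

    report = pd.DataFrame(
        {"F": f_stat, "P": p_val, "P_adj": p_adj, "kept": kept},
        index=expr.values.index,
    )
    logger.info(
        "anova_filter: kept %d / %d probes (alpha=%g, adjust=%s)",
        int(kept.sum()), len(kept), criteria.alpha, criteria.adjust,
    )
    filtered = ExpressionMatrix(
        values=expr.values.loc[kept],
        sample_annotations=expr.sample_annotations,
    )
    return filtered, report
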