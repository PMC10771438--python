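"""The genome-wide propensity screen and the cross-protocol intersection.

Per protocol, every filtered probe's per-line replicate-mean expression
is rank-correlated against the PC1 propensity ranking with the exact
small-sample permutation null (n = number of lines); probes with
two-sided exact P at or below alpha form the positive / negative
candidate sets by the sign of r_s.  Candidates surviving across
protocols *with the same sign* are the final markers — a gene positive
in one protocol and negative in another is discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .propensity import PropensityResult
from .rankcorr import (
    CorrelationCall,
    NullDistribution,
    _t_approx_pvalue,
    exact_null,
    exact_pvalue,
)
from .synthetic import ExpressionMatrix

__all__ = ["ScreenResult", "IntersectionResult", "screen_protocol",
           "intersect_candidates"]

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    """Per-protocol screen output.

    ``table`` has one row per tested gene: gene_id, r_s, p_two_sided,
    direction, significant, tied.
    """

    protocol: str
    table: pd.DataFrame
    positive_set: set[str]
    negative_set: set[str]
    n_tested: int
    alpha: float

    @property
    def calls(self) -> list[CorrelationCall]:
        return [
            CorrelationCall(
                gene_id=row.gene_id,
                r_s=row.r_s,
                p_two_sided=row.p_two_sided,
                significant=row.significant,
                direction=row.direction,
                alpha=self.alpha,
                tied=row.tied,
            )
            for row in self.table.itertuples(index=False)
        ]


@dataclass
class IntersectionResult:
    """Sign-concordant candidate intersection across protocols."""

    common_positive: set[str]
    common_negative: set[str]
    provenance: pd.DataFrame  # gene_id, protocol, r_s, p_two_sided, direction
    discordant: set[str] = field(default_factory=set)


def screen_protocol(
    expr: ExpressionMatrix,
    propensity: PropensityResult,
    alpha: float = 0.01,
    null: Optional[NullDistribution] = None,
) -> ScreenResult:
    """Correlate every probe's per-line mean expression against the PC1
    ranking of one protocol.

    Expression replicates are averaged per line before ranking, so each
    gene contributes one intensity rank per line; correlations use the
    exact permutation null for the line count (ties, which cannot occur
    for continuous intensities, fall back to a flagged t approximation).
    """
    line_means = expr.line_means(condition="undifferentiated")
    expr_lines = set(line_means.columns)
    prop_lines = set(propensity.lines)
    if expr_lines != prop_lines:
        raise ValueError(
            "line mismatch between expression and propensity: "
            f"only in expression {sorted(expr_lines - prop_lines)}, "
            f"only in propensity {sorted(prop_lines - expr_lines)}"
        )
    lines = list(propensity.lines)
    n = len(lines)
    if null is None:
        null = exact_null(n)

    x = line_means[lines].to_numpy()
    # ascending rank of the propensity index per line (rank_lines uses
    # 1 = highest score, so invert to keep "higher PC1 = higher rank")
    prop_rank = (n + 1 - propensity.pc1_rank.loc[lines].to_numpy()).astype(np.int64)

    gene_ranks = stats.rankdata(x, axis=1)
    tied_mask = np.any(np.abs(gene_ranks - np.round(gene_ranks)) > 0, axis=1) | (
        np.ptp(x, axis=1) == 0
    )
    # untied integer ranks could still repeat values; detect real ties
    sorted_ranks = np.sort(gene_ranks, axis=1)
    tied_mask |= np.any(np.diff(sorted_ranks, axis=1) == 0, axis=1)

    d = gene_ranks - prop_rank[None, :]
    sum_d2 = (d * d).sum(axis=1)
    m = n ** 3 - n
    r_s = 1.0 - 6.0 * sum_d2 / m

    # exact two-sided P via the null's tail function over sum d^2
    p = np.empty(len(r_s))
    tail = _two_sided_tail_lookup(null)
    untied = ~tied_mask
    p[untied] = tail(np.round(sum_d2[untied]).astype(np.int64))
    for i in np.flatnonzero(tied_mask):
        if np.ptp(x[i]) == 0:  # constant gene: association undefined
            r_s[i], p[i] = 0.0, 1.0
            continue
        rr = float(np.corrcoef(gene_ranks[i], prop_rank)[0, 1])
        r_s[i] = rr
        p[i] = _t_approx_pvalue(rr, n)

    significant = p <= alpha
    direction = np.where(r_s >= 0, "+", "-")
    table = pd.DataFrame(
        {
            "gene_id": line_means.index,
            "r_s": r_s,
            "p_two_sided": p,
            "direction": direction,
            "significant": significant,
            "tied": tied_mask,
        }
    ).reset_index(drop=True)
    pos = set(table.loc[table.significant & (table.direction == "+"), "gene_id"])
    neg = set(table.loc[table.significant & (table.direction == "-"), "gene_id"])
    logger.info(
        "screen[%s]: %d tested, %d positive, %d negative (alpha=%g)",
        propensity.protocol, len(table), len(pos), len(neg), alpha,
    )
    return ScreenResult(
        protocol=propensity.protocol,
        table=table,
        positive_set=pos,
        negative_set=neg,
        n_tested=len(table),
        alpha=alpha,
    )


def _two_sided_tail_lookup(null: NullDistribution):
    """Vectorized sum_d2 -> two-sided exact P, honoring the symmetry of
    the null about sum_d2 = (n^3 - n) / 6."""
    max_s = null.n * (null.n ** 2 - 1) // 3
    counts = np.zeros(max_s + 1, dtype=np.int64)
    counts[null.sum_d2] = null.counts
    # |r(s)| >= |r(s0)|  <=>  s <= s0 or s >= max_s - s0
    cum_low = np.cumsum(counts)
    cum_high = np.cumsum(counts[::-1])[::-1]

    def tail(s: np.ndarray) -> np.ndarray:
        s = np.clip(s, 0, max_s)
        mirror = np.clip(max_s - s, 0, max_s)
        lo = np.where(s <= mirror, s, mirror)
        two = cum_low[lo] + cum_high[max_s - lo]
        # when s is exactly central (r_s = 0), both tails are everything
        return np.minimum(two / null.total, 1.0)

    return tail


def intersect_candidates(results: Sequence[ScreenResult]) -> IntersectionResult:
    """Sign-concordant intersection of significant candidates.

    ``common_positive`` / ``common_negative`` are the genes significant
    with the same sign in *every* protocol; genes significant with
    opposite signs in different protocols are excluded and reported in
    ``discordant``.
    """
    if len(results) < 2:
        raise ValueError("intersection needs >= 2 screen results")
    universes = [set(r.table["gene_id"]) for r in results]
    if len(set(map(frozenset, universes))) != 1:
        raise ValueError("screen results cover different gene universes")

    common_pos = set.intersection(*[r.positive_set for r in results])
    common_neg = set.intersection(*[r.negative_set for r in results])
    any_pos = set.union(*[r.positive_set for r in results])
    any_neg = set.union(*[r.negative_set for r in results])
    discordant = any_pos & any_neg
    if discordant:
        logger.info(
            "%d gene(s) significant with opposite signs across protocols "
            "excluded: %s", len(discordant), sorted(discordant),
        )

    keep = common_pos | common_neg | discordant
    rows = []
    for r in results:
        sub = r.table[r.table["gene_id"].isin(keep)]
        for row in sub.itertuples(index=False):
            rows.append(
                {
                    "gene_id": row.gene_id,
                    "protocol": r.protocol,
                    "r_s": row.r_s,
                    "p_two_sided": row.p_two_sided,
                    "direction": row.direction,
                }
            )
    provenance = pd.DataFrame(
        rows, columns=["gene_id", "protocol", "r_s", "p_two_sided", "direction"]
    )
    return IntersectionResult(
        common_positive=common_pos,
        common_negative=common_neg,
        provenance=provenance,
        discordant=discordant,
    )
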