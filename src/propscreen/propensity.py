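"""The per-line differentiation-propensity index.

Marker replicate means are z-scored per marker and summarized by the
first principal component of the marker correlation matrix.  PC1 is
sign-oriented so that its loadings sum positive — higher PC1 means
uniformly higher marker expression, i.e. stronger NS/PC differentiation —
and lines are ranked in descending PC1 (rank 1 = highest propensity).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "PropensityResult",
    "zscore_markers",
    "pc1",
    "rank_lines",
    "propensity_from_panel",
]


@dataclass(frozen=True)
class PropensityResult:
    """PC1 propensity index for a panel of lines.

    ``pc1_rank`` maps rank 1 to the highest PC1 score; ``loadings`` is
    the unit-norm leading eigenvector; ``explained_variance`` is in
    percent of total variance.
    """

    lines: tuple[str, ...]
    pc1_score: pd.Series
    pc1_rank: pd.Series
    loadings: pd.Series
    explained_variance: float
    protocol: str = "custom"
    tied_ranks: bool = False


def zscore_markers(table: pd.DataFrame) -> pd.DataFrame:
    """Standardize each marker column to mean 0, SD 1 (denominator n-1).

    Raises if a marker has zero spread (its z-scores would be undefined).
    """
    if len(table) < 2:
        raise ValueError("z-scoring needs at least 2 lines")
    sd = table.std(axis=0, ddof=1)
    zero = sd.index[sd == 0.0]
    if len(zero):
        raise ValueError(f"marker(s) with zero standard deviation: {list(zero)}")
    return (table - table.mean(axis=0)) / sd


def pc1(table: pd.DataFrame, protocol: str = "custom") -> PropensityResult:
    """First principal component of a standardized line x marker table.

    Scores are the projection onto the leading eigenvector of the marker
    correlation matrix; explained variance is the leading eigenvalue as a
    percentage of the eigenvalue total.  The sign is oriented so the
    loadings sum positive (ties broken toward a non-negative first
    loading).
    """
    values = table.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("pc1 requires finite values")
    n, m = values.shape
    if n <= m:
        import warnings

        warnings.warn(
            f"pc1 with {n} lines and {m} markers: more lines than markers "
            "is recommended",
            stacklevel=2,
        )
    corr = values.T @ values / (n - 1)  # correlation matrix of z-scored data
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    vec = eigvecs[:, order[0]]
    s = vec.sum()
    if s < 0 or (s == 0 and vec[0] < 0):
        vec = -vec
    scores = pd.Series(values @ vec, index=table.index, name="pc1_score")
    loadings = pd.Series(vec, index=table.columns, name="pc1_loading")
    explained = float(100.0 * eigvals[0] / eigvals.sum())
    result = PropensityResult(
        lines=tuple(table.index),
        pc1_score=scores,
        pc1_rank=pd.Series(0, index=table.index),  # filled by rank_lines
        loadings=loadings,
        explained_variance=explained,
        protocol=protocol,
    )
    return rank_lines(result)


def rank_lines(result: PropensityResult) -> PropensityResult:
    """Rank lines in descending PC1 (rank 1 = highest score).

    Exact score ties are broken by lexicographic line id and flagged via
    ``tied_ranks``.
    """
    scores = result.pc1_score
    tied = scores.duplicated().any()
    order = sorted(scores.index, key=lambda ln: (-scores[ln], ln))
    ranks = pd.Series(
        {ln: i + 1 for i, ln in enumerate(order)}, name="pc1_rank"
    ).reindex(scores.index)
    return replace(result, pc1_rank=ranks, tied_ranks=bool(tied))


def propensity_from_panel(panel) -> PropensityResult:
    """Marker panel -> replicate means -> z-score -> PC1, in one step."""
    from .preprocess import aggregate_replicates

    means = aggregate_replicates(panel)
    return pc1(zscore_markers(means), protocol=panel.protocol)
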