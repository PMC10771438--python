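"""Synthetic study data with known ground truth.

Emulates the data context of a multi-line hiPSC biomarker screen: a log2
expression atlas over ~3,362 line-variable probes (10 lines, replicated),
two qPCR marker panels (PAX6/SOX1/NES analogues, relative expression,
3 replicates) read out after neural differentiation by a suspension and an
adhesion protocol, and a knockdown-vs-control time course.  A latent
per-line differentiation propensity drives both marker panels and the
planted propensity-correlated genes, so every downstream stage can be
tested against recorded truth.

Planted genes realize a target rank correlation by construction: the
gene's line ordering is a permutation of the latent propensity ordering at
the nearest achievable even sum of squared rank differences to
(1 - rho) * (n^3 - n) / 6, so at rho = 1 (and zero noise) the planted rank
correlation is exactly +/-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .rankcorr import permutation_with_sum_d2

__all__ = [
    "PanelConfig",
    "SyntheticTruth",
    "ExpressionMatrix",
    "MarkerPanel",
    "simulate_panel",
    "simulate_kd_timecourse",
]

MARKER_NAMES = ("PAX6", "SOX1", "NES")
#: Relative-expression baselines per marker (dimensionless); the spread
#: across lines, not the baseline, carries the propensity signal.
MARKER_BASELINES = (1.0, 0.7, 1.3)
#: Log2 spread of a planted gene's per-line means across the line panel.
PLANTED_AMPLITUDE = 2.0


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Log2 intensities, probes x samples, with per-sample annotations.

    ``values``: DataFrame indexed by probe id, columns sample ids.
    ``sample_annotations``: DataFrame indexed by sample id with columns
    ``line``, ``replicate``, ``condition``, ``day``.
    """

    values: pd.DataFrame
    sample_annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate probe ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        missing = set(self.values.columns) - set(self.sample_annotations.index)
        if missing:
            raise ValueError(f"samples without annotation: {sorted(missing)}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def line_means(self, condition: Optional[str] = None,
                   day: Optional[int] = None) -> pd.DataFrame:
        """Per-line replicate-mean expression (probes x lines)."""
        ann = self.sample_annotations.loc[self.sample_ids]
        keep = pd.Series(True, index=ann.index)
        if condition is not None:
            keep &= ann["condition"] == condition
        if day is not None:
            keep &= ann["day"] == day
        cols = ann.index[keep]
        groups = ann.loc[cols, "line"]
        return self.values[cols].T.groupby(groups).mean().T


@dataclass
class MarkerPanel:
    """Per-line qPCR marker replicates for one differentiation protocol.

    ``data``: long-format DataFrame with columns line, marker, replicate,
    value (relative expression, positive).
    """

    protocol: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"line", "marker", "replicate", "value"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"panel data needs columns {sorted(required)}")
        if (self.data["value"] <= 0).any():
            raise ValueError("relative expression values must be positive")
        counts = self.data.groupby(["line", "marker"])["replicate"].count()
        if counts.nunique() != 1:
            raise ValueError("unequal replicate counts across (line, marker)")

    @property
    def lines(self) -> list[str]:
        return sorted(self.data["line"].unique())

    @property
    def markers(self) -> list[str]:
        return list(pd.unique(self.data["marker"]))

    def line_marker_means(self) -> pd.DataFrame:
        """Replicate means, lines x markers."""
        wide = self.data.pivot_table(
            index="line", columns="marker", values="value", aggfunc="mean"
        )
        return wide[self.markers]


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator."""

    latent_propensity: pd.Series  # per line
    planted: pd.DataFrame  # gene_id, direction (+/-), target_sum_d2
    shared_negative_id: Optional[str]
    marker_means: dict[str, pd.DataFrame]  # protocol -> lines x markers

    def __post_init__(self) -> None:
        bad = set(self.planted["direction"]) - {"+", "-"}
        if bad:
            raise ValueError(f"direction labels must be +/-, got {bad}")

    @property
    def planted_gene_ids(self) -> list[str]:
        return list(self.planted["gene_id"])


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PanelConfig:
    """Study conditions for the synthetic panel.

    Defaults mirror the emulated study: 10 hiPSC lines, 3,362
    line-variable probes, 6 expression replicates, 3 qPCR replicates,
    3 NS/PC markers, marker dynamic ranges of 5-fold (suspension) and
    15-fold (adhesion).
    """

    n_lines: int = 10
    n_probes: int = 3362
    n_expr_replicates: int = 6
    n_qpcr_replicates: int = 3
    n_markers: int = 3
    planted_pos: int = 2
    planted_neg: int = 2
    planted_rho: float = 0.9
    suspension_fold_range: float = 5.0
    adhesion_fold_range: float = 15.0
    noise_sd: float = 0.2
    #: Fraction of non-planted probes given line-specific offsets (the
    #: probes a line-wise ANOVA filter should keep); the rest are pure
    #: noise and should be rejected.
    line_effect_frac: float = 0.5
    line_effect_sd: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.n_lines < 4:
            raise ValueError(f"n_lines must be >= 4, got {self.n_lines}")
        if self.planted_pos < 0 or self.planted_neg < 0:
            raise ValueError("planted counts must be non-negative")
        if self.planted_pos + self.planted_neg >= self.n_probes:
            raise ValueError(
                "planted_pos + planted_neg must be < n_probes "
                f"({self.planted_pos}+{self.planted_neg} vs {self.n_probes})"
            )
        if not 0.0 <= self.planted_rho <= 1.0:
            raise ValueError(
                f"planted_rho must be in [0, 1], got {self.planted_rho}"
            )
        for name in ("suspension_fold_range", "adhesion_fold_range"):
            if getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be > 1, got {getattr(self, name)}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0.0 <= self.line_effect_frac <= 1.0:
            raise ValueError("line_effect_frac must be in [0, 1]")
        for name in ("n_expr_replicates", "n_qpcr_replicates", "n_markers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _line_ids(n: int) -> list[str]:
    return [f"line{i + 1:02d}" for i in range(n)]


def _probe_ids(n: int) -> list[str]:
    return [f"probe{i + 1:05d}" for i in range(n)]


def _planted_target_sum_d2(n: int, rho: float) -> int:
    """Nearest achievable even sum d^2 to the one implying r_s = rho."""
    s = (1.0 - rho) * (n ** 3 - n) / 6.0
    t = int(round(s / 2.0)) * 2
    return min(max(t, 0), n * (n * n - 1) // 3)


def simulate_panel(
    config: PanelConfig,
) -> tuple[ExpressionMatrix, MarkerPanel, MarkerPanel, SyntheticTruth]:
    """Generate the undifferentiated expression atlas, the two protocol
    marker panels, and the recorded truth.

    Returns ``(expression, suspension_panel, adhesion_panel, truth)``.
    Identical configs (including seed) give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_lines
    lines = _line_ids(n)
    probes = _probe_ids(config.n_probes)

    latent = pd.Series(rng.uniform(size=n), index=lines, name="latent_propensity")
    latent_ranks = latent.rank(method="first").astype(int).to_numpy()  # 1..n asc

    # --- planted genes ---------------------------------------------------
    n_planted = config.planted_pos + config.planted_neg
    planted_idx = rng.choice(config.n_probes, size=n_planted, replace=False)
    directions = ["+"] * config.planted_pos + ["-"] * config.planted_neg
    target = _planted_target_sum_d2(n, config.planted_rho)

    mean_expr = np.empty((config.n_probes, n))
    baselines = rng.uniform(5.0, 11.0, size=config.n_probes)
    mean_expr[:] = baselines[:, None]

    # background line effects on a fraction of non-planted probes
    non_planted = np.setdiff1d(np.arange(config.n_probes), planted_idx)
    n_eff = int(round(config.line_effect_frac * non_planted.size))
    eff_idx = rng.choice(non_planted, size=n_eff, replace=False)
    mean_expr[eff_idx] += rng.normal(0.0, config.line_effect_sd, size=(n_eff, n))

    planted_rows = []
    for gi, direction in zip(planted_idx, directions):
        q = permutation_with_sum_d2(n, target, rng)
        gene_ranks = q[latent_ranks - 1]  # perm of 1..n, sum d^2 = target vs latent
        grade = (gene_ranks - 1) / (n - 1) - 0.5  # in [-0.5, 0.5], monotone in rank
        sign = 1.0 if direction == "+" else -1.0
        mean_expr[gi] = baselines[gi] + sign * PLANTED_AMPLITUDE * grade
        planted_rows.append(
            {"gene_id": probes[gi], "direction": direction, "target_sum_d2": target}
        )
    planted_df = pd.DataFrame(
        planted_rows, columns=["gene_id", "direction", "target_sum_d2"]
    )
    negatives = planted_df.loc[planted_df["direction"] == "-", "gene_id"]
    shared_negative = negatives.iloc[0] if len(negatives) else None

    # --- replicate-level expression samples ------------------------------
    reps = config.n_expr_replicates
    sample_ids = [f"{ln}_r{k + 1}" for ln in lines for k in range(reps)]
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_probes, n * reps))
    values = np.repeat(mean_expr, reps, axis=1) + noise
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=probes, columns=sample_ids),
        sample_annotations=pd.DataFrame(
            {
                "line": [ln for ln in lines for _ in range(reps)],
                "replicate": [k + 1 for _ in lines for k in range(reps)],
                "condition": "undifferentiated",
                "day": 0,
            },
            index=sample_ids,
        ),
    )

    # --- marker panels ----------------------------------------------------
    u = (latent - latent.min()) / (latent.max() - latent.min())  # in [0, 1]
    marker_names = [
        MARKER_NAMES[i] if i < len(MARKER_NAMES) else f"marker{i + 1}"
        for i in range(config.n_markers)
    ]
    marker_base = [
        MARKER_BASELINES[i % len(MARKER_BASELINES)] for i in range(config.n_markers)
    ]
    panels: dict[str, MarkerPanel] = {}
    marker_means: dict[str, pd.DataFrame] = {}
    for protocol, fold in (
        ("suspension", config.suspension_fold_range),
        ("adhesion", config.adhesion_fold_range),
    ):
        means = pd.DataFrame(
            {
                m: base * np.power(fold, u.to_numpy())
                for m, base in zip(marker_names, marker_base)
            },
            index=lines,
        )
        rows = []
        for ln in lines:
            for m in marker_names:
                eps = rng.normal(0.0, config.noise_sd, size=config.n_qpcr_replicates)
                vals = means.at[ln, m] * np.exp2(eps)
                for k, v in enumerate(vals):
                    rows.append(
                        {"line": ln, "marker": m, "replicate": k + 1, "value": v}
                    )
        panels[protocol] = MarkerPanel(protocol=protocol, data=pd.DataFrame(rows))
        marker_means[protocol] = means

    truth = SyntheticTruth(
        latent_propensity=latent,
        planted=planted_df,
        shared_negative_id=shared_negative,
        marker_means=marker_means,
    )
    return expr, panels["suspension"], panels["adhesion"], truth


def simulate_kd_timecourse(
    config: PanelConfig,
    n_de_genes: int,
    log2fc: float,
    days: Sequence[int] = (7, 14, 21),
    n_replicates: int = 3,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Knockdown-vs-control expression over a differentiation time course.

    ``n_de_genes`` genes get a mean log2 fold difference of ``log2fc``
    (knockdown minus control) at every day; alternate planted genes carry
    the opposite sign so both tails are populated.  Returns the matrix and
    a truth table (gene_id, planted_log2fc).
    """
    config.validate()
    if n_de_genes >= config.n_probes:
        raise ValueError(
            f"n_de_genes ({n_de_genes}) must be < n_probes ({config.n_probes})"
        )
    if len(days) == 0:
        raise ValueError("days must be non-empty")
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")

    rng = np.random.default_rng(config.seed)
    probes = _probe_ids(config.n_probes)
    base = rng.uniform(5.0, 11.0, size=config.n_probes)
    de_idx = rng.choice(config.n_probes, size=n_de_genes, replace=False)
    effects = np.zeros(config.n_probes)
    signs = np.where(np.arange(n_de_genes) % 2 == 0, 1.0, -1.0)
    effects[de_idx] = signs * log2fc

    cols, ann_rows, blocks = [], [], []
    for day in days:
        day_shift = rng.normal(0.0, 0.25, size=config.n_probes)  # shared drift
        for condition, eff in (("control", 0.0), ("kd", 1.0)):
            mean = base + day_shift + eff * effects
            for k in range(n_replicates):
                sid = f"{condition}_d{day}_r{k + 1}"
                cols.append(sid)
                ann_rows.append(
                    {
                        "sample_id": sid,
                        "line": condition,
                        "replicate": k + 1,
                        "condition": condition,
                        "day": day,
                    }
                )
                blocks.append(
                    mean + rng.normal(0.0, config.noise_sd, size=config.n_probes)
                )
    values = pd.DataFrame(np.column_stack(blocks), index=probes, columns=cols)
    ann = pd.DataFrame(ann_rows).set_index("sample_id")
    truth = pd.DataFrame(
        {"gene_id": [probes[i] for i in de_idx], "planted_log2fc": effects[de_idx]}
    )
    return ExpressionMatrix(values=values, sample_annotations=ann), truth
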