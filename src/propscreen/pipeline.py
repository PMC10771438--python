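"""End-to-end orchestration: filter -> propensity -> screen -> intersect.

Every intermediate table is written to the output directory and a run
manifest (JSON) records the package version, seed, parameters and a
sha256 checksum of each artifact, so identical configurations give
identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import io as psio
from .preprocess import FilterCriteria, anova_filter
from .propensity import propensity_from_panel
from .rankcorr import critical_value, exact_null
from .screen import IntersectionResult, intersect_candidates, screen_protocol
from .synthetic import ExpressionMatrix, MarkerPanel, PanelConfig, simulate_panel

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_full_screen"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration of a full screening run.

    When ``expression_tsv`` is None the synthetic generator supplies all
    inputs from ``panel`` (whose seed is the run seed).
    """

    out_dir: Path
    panel: PanelConfig = field(default_factory=PanelConfig)
    filter_criteria: FilterCriteria = field(default_factory=FilterCriteria)
    alpha_screen: float = 0.01
    protocols: tuple[str, ...] = ("suspension", "adhesion")
    expression_tsv: Optional[Path] = None
    samples_tsv: Optional[Path] = None
    panel_tsvs: tuple[Path, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_screen < 1.0:
            raise ValueError(
                f"alpha_screen must be in (0, 1), got {self.alpha_screen}"
            )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_screen(config: PipelineConfig) -> IntersectionResult:
    """Run the complete screen and write all artifacts under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    # --- inputs -----------------------------------------------------------
    stage = "inputs"
    try:
        if config.expression_tsv is not None:
            expr = psio.read_expression(config.expression_tsv, config.samples_tsv)
            panels = [psio.read_marker_panel(p) for p in config.panel_tsvs]
            panels = {p.protocol: p for p in panels}
        else:
            expr, susp, adh, truth = simulate_panel(config.panel)
            panels = {"suspension": susp, "adhesion": adh}
            psio.write_expression(
                expr, out / "expression.tsv", out / "samples.tsv"
            )
            for name, panel in panels.items():
                psio.write_marker_panel(panel, out / f"panel_{name}.tsv")
            psio.write_truth(truth, out / "truth.tsv")
            artifacts.update(
                {
                    "expression.tsv": out / "expression.tsv",
                    "samples.tsv": out / "samples.tsv",
                    "panel_suspension.tsv": out / "panel_suspension.tsv",
                    "panel_adhesion.tsv": out / "panel_adhesion.tsv",
                    "truth.tsv": out / "truth.tsv",
                }
            )
        missing = [p for p in config.protocols if p not in panels]
        if missing:
            raise ValueError(f"no marker panel for protocol(s) {missing}")
    except Exception as e:  # noqa: BLE001 - stage attribution
        raise PipelineError(stage, e) from e

    # --- probe filter -----------------------------------------------------
    stage = "filter"
    try:
        filtered, report = anova_filter(
            expr, config.filter_criteria, condition="undifferentiated"
        )
        psio.write_filter_report(report, out / "filter_report.tsv")
        artifacts["filter_report.tsv"] = out / "filter_report.tsv"
        logger.info("filter: %d -> %d probes", len(report), len(filtered.probe_ids))
    except Exception as e:
        raise PipelineError(stage, e) from e

    # --- achievable significance level ------------------------------------
    n_lines = len(expr.sample_annotations["line"].unique())
    null = exact_null(n_lines)
    cv = critical_value(n_lines, config.alpha_screen, null)
    if not cv.attainable:
        warnings.warn(
            f"alpha_screen={config.alpha_screen} is unachievable at "
            f"n={n_lines}: {cv.reason}; candidate sets will be empty",
            stacklevel=2,
        )

    # --- per-protocol propensity and screen -------------------------------
    screens = []
    for protocol in config.protocols:
        stage = f"propensity[{protocol}]"
        try:
            prop = propensity_from_panel(panels[protocol])
            psio.write_propensity(prop, out / f"propensity_{protocol}.tsv")
            artifacts[f"propensity_{protocol}.tsv"] = out / f"propensity_{protocol}.tsv"
        except Exception as e:
            raise PipelineError(stage, e) from e
        stage = f"screen[{protocol}]"
        try:
            res = screen_protocol(filtered, prop, config.alpha_screen, null)
            psio.write_screen_table(res, out / f"screen_{protocol}.tsv")
            artifacts[f"screen_{protocol}.tsv"] = out / f"screen_{protocol}.tsv"
            screens.append(res)
        except Exception as e:
            raise PipelineError(stage, e) from e

    # --- intersection ------------------------------------------------------
    stage = "intersect"
    try:
        inter = intersect_candidates(screens)
        psio.write_intersection(inter, out / "candidates.tsv")
        artifacts["candidates.tsv"] = out / "candidates.tsv"
    except Exception as e:
        raise PipelineError(stage, e) from e

    # --- manifest ----------------------------------------------------------
    from importlib.metadata import version

    try:
        pkg_version = version("propscreen")
    except Exception:  # pragma: no cover - not installed
        pkg_version = "unknown"
    manifest = {
        "package": "propscreen",
        "version": pkg_version,
        "seed": config.panel.seed,
        "alpha_screen": config.alpha_screen,
        "filter": dataclasses.asdict(config.filter_criteria),
        "panel": dataclasses.asdict(config.panel),
        "protocols": list(config.protocols),
        "n_candidates": {
            "common_positive": sorted(inter.common_positive),
            "common_negative": sorted(inter.common_negative),
            "discordant": sorted(inter.discordant),
        },
        "checksums": {name: _sha256(path) for name, path in sorted(artifacts.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return inter
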