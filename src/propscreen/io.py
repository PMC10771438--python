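"""TSV readers and writers for every pipeline artifact.

All tables are plain tab-separated text.  The expression matrix is two
files: a values table (first column ``probe_id``, header row of sample
ids) and a sample sheet (``sample_id``, ``line``, ``replicate``,
``condition``, ``day``).  Marker panels are long format (``line``,
``marker``, ``replicate``, ``value``, ``protocol``).  Propensity results
carry their metadata (protocol, explained variance, loadings) in ``#``
comment lines above the header.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .propensity import PropensityResult
from .rankcorr import NullDistribution
from .screen import IntersectionResult, ScreenResult
from .synthetic import ExpressionMatrix, MarkerPanel, PanelConfig, SyntheticTruth

PathLike = Union[str, Path]

__all__ = [
    "write_expression", "read_expression",
    "write_marker_panel", "read_marker_panel",
    "write_truth",
    "write_propensity", "read_propensity",
    "write_screen_table", "write_intersection",
    "write_null_distribution", "write_filter_report",
    "load_panel_config", "dump_panel_config",
]


def write_expression(expr: ExpressionMatrix, values_path: PathLike,
                     samples_path: PathLike) -> None:
    expr.values.rename_axis("probe_id").to_csv(values_path, sep="\t")
    expr.sample_annotations.rename_axis("sample_id").to_csv(samples_path, sep="\t")


def read_expression(values_path: PathLike, samples_path: PathLike) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="probe_id")
    ann = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    return ExpressionMatrix(values=values, sample_annotations=ann)


def write_marker_panel(panel: MarkerPanel, path: PathLike) -> None:
    out = panel.data.copy()
    out["protocol"] = panel.protocol
    out.to_csv(path, sep="\t", index=False)


def read_marker_panel(path: PathLike) -> MarkerPanel:
    data = pd.read_csv(path, sep="\t")
    protocols = data["protocol"].unique()
    if len(protocols) != 1:
        raise ValueError(f"expected a single protocol per panel file, got {protocols}")
    return MarkerPanel(
        protocol=str(protocols[0]),
        data=data.drop(columns=["protocol"]),
    )


def write_truth(truth: SyntheticTruth, path: PathLike) -> None:
    """Latent propensity and planted-gene table as one tidy TSV."""
    rows = [
        {"record": "latent", "id": ln, "value": v, "direction": ""}
        for ln, v in truth.latent_propensity.items()
    ]
    rows += [
        {
            "record": "planted",
            "id": r.gene_id,
            "value": r.target_sum_d2,
            "direction": r.direction,
        }
        for r in truth.planted.itertuples(index=False)
    ]
    if truth.shared_negative_id is not None:
        rows.append(
            {
                "record": "shared_negative",
                "id": truth.shared_negative_id,
                "value": "",
                "direction": "-",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_propensity(result: PropensityResult, path: PathLike) -> None:
    path = Path(path)
    meta = {
        "protocol": result.protocol,
        "explained_variance": result.explained_variance,
        "tied_ranks": result.tied_ranks,
        "loadings": {m: float(v) for m, v in result.loadings.items()},
    }
    body = pd.DataFrame(
        {
            "line": list(result.lines),
            "pc1_score": result.pc1_score.loc[list(result.lines)].to_numpy(),
            "pc1_rank": result.pc1_rank.loc[list(result.lines)].to_numpy(),
        }
    )
    with path.open("w") as fh:
        fh.write(f"# propensity {json.dumps(meta)}\n")
        body.to_csv(fh, sep="\t", index=False)


def read_propensity(path: PathLike) -> PropensityResult:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("# propensity "):
            raise ValueError(f"{path} is not a propensity TSV")
        meta = json.loads(header[len("# propensity "):])
        body = pd.read_csv(fh, sep="\t")
    body = body.set_index("line")
    return PropensityResult(
        lines=tuple(body.index),
        pc1_score=body["pc1_score"],
        pc1_rank=body["pc1_rank"],
        loadings=pd.Series(meta["loadings"]),
        explained_variance=float(meta["explained_variance"]),
        protocol=meta["protocol"],
        tied_ranks=bool(meta["tied_ranks"]),
    )


def write_screen_table(result: ScreenResult, path: PathLike) -> None:
    result.table.to_csv(path, sep="\t", index=False)


def write_intersection(result: IntersectionResult, path: PathLike) -> None:
    """Candidate table in a per-protocol, per-direction layout."""
    prov = result.provenance.copy()
    label = np.where(
        prov["gene_id"].isin(result.common_positive), "common_positive",
        np.where(
            prov["gene_id"].isin(result.common_negative), "common_negative",
            "discordant",
        ),
    )
    prov.insert(0, "status", label)
    prov.sort_values(["status", "gene_id", "protocol"]).to_csv(
        path, sep="\t", index=False
    )


def write_filter_report(report: pd.DataFrame, path: PathLike) -> None:
    report.rename_axis("probe_id").to_csv(path, sep="\t")


def write_null_distribution(null: NullDistribution, path: PathLike) -> None:
    support = null.support
    order = np.argsort(support)[::-1]  # descending r_s
    df = pd.DataFrame(
        {
            "r_s": support[order],
            "sum_d2": null.sum_d2[order],
            "count": null.counts[order],
        }
    )
    # two-sided cumulative tail P at each support value
    from .rankcorr import exact_pvalue

    df["cum_two_sided_p"] = [exact_pvalue(v, null) for v in df["r_s"]]
    df.to_csv(path, sep="\t", index=False)


def load_panel_config(path: PathLike) -> PanelConfig:
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PanelConfig(**raw)
    cfg.validate()
    return cfg


def dump_panel_config(config: PanelConfig, path: PathLike) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(config.__dict__, fh, sort_keys=False)
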