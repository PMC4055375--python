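"""Table rendering and machine-readable result documents.

The three report tables mirror the shape conventional for this design:

* treatment decisions per vignette with the paired base-case comparisons;
* per-model agreement per vignette with the pairwise and pooled contrasts;
* elicited benefit/harm ratio summaries per vignette.

Tables are emitted as CSV and GitHub-style Markdown; all statistics are
also collected into one JSON-serializable results document with provenance
(package version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "to_markdown_table",
    "decision_table",
    "agreement_table_rendered",
    "calibration_table",
    "results_document",
    "config_hash",
]


def to_markdown_table(df: pd.DataFrame, float_fmt: str = "{:.3g}") -> str:
    """Render a DataFrame as a GitHub-flavored Markdown table."""

    def fmt(value: Any) -> str:
        if isinstance(value, float):
            if np.isnan(value):
                return ""
            return float_fmt.format(value)
        return str(value)

    header = "| " + " | ".join(map(str, df.columns)) + " |"
    rule = "|" + "|".join([" --- "] * len(df.columns)) + "|"
    body = ["| " + " | ".join(fmt(v) for v in row) + " |" for row in df.itertuples(index=False)]
    return "\n".join([header, rule, *body])


def decision_table(proportions: pd.DataFrame, effects: pd.DataFrame) -> pd.DataFrame:
    """Treat / no-treat counts per vignette with base-case comparisons."""
    merged = proportions.copy()
    pvals = {}
    for _, row in effects.iterrows():
        level = row["comparison"].replace("base vs ", "")
        pvals[(row["condition"], level)] = row["p_value"]
    merged["p_vs_base"] = [
        pvals.get((r["condition"], r["risk_level"]), np.nan)
        for _, r in merged.iterrows()
    ]
    return merged


def agreement_table_rendered(
    summary: pd.DataFrame, per_vignette: pd.DataFrame
) -> pd.DataFrame:
    """Per-model agreement per vignette with pairwise exact-test p-values."""
    pivot = per_vignette.pivot(
        index="vignette_id", columns="contrast", values="p_value"
    )
    out = summary.merge(pivot, on="vignette_id", how="left")
    # attach each pairwise p-value only to the row of its first-named model
    for contrast in pivot.columns:
        first = contrast.split("_vs_")[0]
        out.loc[out["model"] != first, contrast] = np.nan
    return out


def calibration_table(calibration: pd.DataFrame) -> pd.DataFrame:
    """Benefit/harm ratio summaries, rounded for display."""
    out = calibration.copy()
    for col in ("mean", "min", "median", "max"):
        out[col] = out[col].round(2)
    return out


def config_hash(config: Any) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    if hasattr(config, "model_dump"):
        config = config.model_dump()
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="records"))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def results_document(
    *,
    seed: int | None,
    config: Any,
    proportions: pd.DataFrame,
    effects: pd.DataFrame,
    agreement_summary: pd.DataFrame,
    comparison,
    calibration: pd.DataFrame,
    n_excluded: int,
    version: str,
) -> dict:
    """Assemble the machine-readable results document."""
    pooled = comparison.pooled
    return _jsonable(
        {
            "provenance": {
                "tool": "treatthresh",
                "version": version,
                "seed": seed,
                "config_hash": config_hash(config) if config is not None else None,
            },
            "n_excluded_uninformative": n_excluded,
            "treat_proportions": proportions,
            "risk_level_comparisons": effects,
            "agreement_summary": agreement_summary,
            "model_comparison": {
                "per_vignette": comparison.per_vignette,
                "agreement_by_model": comparison.agreement_by_model,
                "pooled": {
                    "or_table": pooled.or_table,
                    "sigma": pooled.sigma,
                    "loglik": pooled.loglik,
                    "null_loglik": pooled.null_loglik,
                    "converged": pooled.converged,
                    "quadrature_order": pooled.quadrature_order,
                    "separation": pooled.separation,
                    "penalized": pooled.penalized,
                },
            },
            "bh_calibration": calibration,
        }
    )
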