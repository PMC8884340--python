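"""Declarative analysis plans: run the statistical battery from YAML.

A plan declares four block types — ``anovas``, ``contrast_families``,
``pca``, and ``regressions`` — evaluated against the long-format analysis
table (participant × condition × mode) and an optional participant-level
covariate table.  Regressions may reference a PCA block's factor scores as
predictors with ``{pca: NAME}``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from bifluent.stats import (
    backward_stepwise,
    mixed_anova,
    pca_varimax,
    planned_contrasts,
)

__all__ = ["run_plan", "load_plan"]


def load_plan(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}


def _filter(frame: pd.DataFrame, spec: dict) -> pd.DataFrame:
    out = frame
    if spec.get("group"):
        out = out[out["group"] == spec["group"]]
    if spec.get("mode") and "mode" in out:
        out = out[out["mode"] == spec["mode"]]
    return out


def _pivot_dv(table: pd.DataFrame, dv: str, condition: str) -> pd.Series:
    rows = table[table["condition"] == condition]
    return rows.set_index("participant_id")[dv]


def run_plan(
    plan: dict,
    table: pd.DataFrame,
    participants: Optional[pd.DataFrame] = None,
) -> dict[str, pd.DataFrame]:
    """Execute every block of a plan; returns one tidy frame per result type."""
    results: dict[str, list[pd.DataFrame]] = {
        "anova": [],
        "contrasts": [],
        "pca_loadings": [],
        "pca_summary": [],
        "regression": [],
    }
    pca_scores: dict[str, pd.DataFrame] = {}

    for spec in plan.get("anovas", []):
        data = _filter(table, spec)
        if spec.get("conditions"):
            data = data[data["condition"].isin(spec["conditions"])]
        res = mixed_anova(
            data,
            dv=spec["dv"],
            within=spec.get("within", "condition"),
            between=spec.get("between", "group"),
        )
        res.insert(0, "name", spec["name"])
        results["anova"].append(res)

    for spec in plan.get("contrast_families", []):
        data = _filter(table, spec)
        contrasts = []
        if spec.get("paired", True):
            for a, b in spec["pairs"]:
                x = _pivot_dv(data, spec["dv"], a)
                y = _pivot_dv(data, spec["dv"], b)
                shared = x.index.intersection(y.index)
                contrasts.append(
                    (f"{a} vs {b}", x.loc[shared].to_numpy(), y.loc[shared].to_numpy(), True)
                )
        else:
            ga, gb = spec["between"]
            for condition in spec["conditions"]:
                rows = table[table["condition"] == condition]
                x = rows.loc[rows["group"] == ga, spec["dv"]].dropna().to_numpy()
                y = rows.loc[rows["group"] == gb, spec["dv"]].dropna().to_numpy()
                contrasts.append((f"{ga} vs {gb} @ {condition}", x, y, False))
        res = planned_contrasts(contrasts)
        res.insert(0, "family", spec["name"])
        results["contrasts"].append(res)

    for spec in plan.get("pca", []):
        source = participants if participants is not None else table
        data = _filter(source, spec)
        cols = spec["columns"]
        block = data.set_index("participant_id")[cols].dropna()
        res = pca_varimax(
            block,
            eigen_threshold=spec.get("eigen_threshold", 1.0),
            loading_threshold=spec.get("loading_threshold", 0.6),
        )
        pca_scores[spec["name"]] = res.scores
        loadings = res.rotated_loadings.copy()
        loadings.insert(0, "variable", loadings.index)
        loadings.insert(0, "name", spec["name"])
        results["pca_loadings"].append(loadings.reset_index(drop=True))
        results["pca_summary"].append(
            pd.DataFrame(
                {
                    "name": spec["name"],
                    "component": res.rotated_loadings.columns,
                    "variance_explained": res.variance_explained,
                }
            )
        )

    for spec in plan.get("regressions", []):
        source = participants if participants is not None else table
        covs = _filter(source, spec).set_index("participant_id")
        y = _pivot_dv(_filter(table, spec), spec["y"]["dv"], spec["y"]["condition"])
        predictor_blocks = []
        for predictor in spec["predictors"]:
            if isinstance(predictor, dict) and "pca" in predictor:
                scores = pca_scores[predictor["pca"]]
                scores = scores.rename(
                    columns={c: f"{predictor['pca']}:{c}" for c in scores.columns}
                )
                predictor_blocks.append(scores)
            else:
                predictor_blocks.append(covs[[predictor]])
        X = pd.concat(predictor_blocks, axis=1)
        joined = X.join(y.rename("__y__"), how="inner").dropna()
        res = backward_stepwise(
            joined["__y__"].to_numpy(),
            joined.drop(columns="__y__"),
            removal_alpha=spec.get("removal_alpha", 0.10),
        )
        coef = res.coefficients.copy()
        coef.insert(0, "term", coef.index)
        coef.insert(0, "name", spec["name"])
        coef["r_squared"] = res.r_squared
        coef["model_F"] = res.f_statistic
        coef["model_p"] = res.model_p
        results["regression"].append(coef.reset_index(drop=True))

    return {
        key: (pd.concat(frames, ignore_index=True) if frames else pd.DataFrame())
        for key, frames in results.items()
    }
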