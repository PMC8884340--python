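"""Fluency difference scores and the participant-level analysis table."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "FdsRecord",
    "compute_fds",
    "build_fds_records",
    "build_analysis_table",
    "COLUMN_DICTIONARY",
]


def compute_fds(ns_correct: float, lf_correct: float) -> float:
    """Fluency difference score: the category-generation vs letter-fluency
    gap as a proportion of category-generation correct responses.

    ``(ns - lf) / ns``; undefined (NaN) when ``ns_correct`` is zero, never a
    division error.  Negative values are legal (letter fluency exceeding
    category generation); the score never exceeds 1.
    """
    if ns_correct < 0 or lf_correct < 0:
        raise ValueError("correct counts must be non-negative")
    if ns_correct == 0:
        return math.nan
    return (ns_correct - lf_correct) / ns_correct


@dataclass(frozen=True)
class FdsRecord:
    participant_id: str
    language: str  # "L1" | "L2"
    ns_correct: float
    lf_correct: float

    @property
    def fds(self) -> float:
        return compute_fds(self.ns_correct, self.lf_correct)


def build_fds_records(
    condition_means: Mapping[tuple[str, str], float]
) -> list[FdsRecord]:
    """Assemble per-participant, per-language FDS records.

    ``condition_means`` maps ``(participant_id, condition)`` to the
    administration-averaged correct count; letter-fluency counts must
    already be aggregated over the language's letters.
    """
    records = []
    participants = sorted({pid for pid, _ in condition_means})
    for pid in participants:
        for slot in ("L1", "L2"):
            ns = condition_means.get((pid, f"NS-{slot}"))
            lf = condition_means.get((pid, f"LF-{slot}"))
            if ns is None or lf is None:
                continue
            records.append(
                FdsRecord(participant_id=pid, language=slot, ns_correct=ns, lf_correct=lf)
            )
    return records


COLUMN_DICTIONARY = {
    "participant_id": "participant identifier",
    "group": "participant group label",
    "condition": "task condition (NS-L1, NS-L2, SS, FS, LF-L1, LF-L2)",
    "mode": "clustering mode used for this row (semantic or phonemic)",
    "mean_correct": "correct count averaged over the two administrations",
    "mean_cluster_size": "mean cluster size, averaged over administrations",
    "n_switches": "number of switches, averaged over administrations",
    "fds": "fluency difference score for the row's language slot, if defined",
    "incomplete": "True when only one administration was available",
}


def build_analysis_table(
    condition_scores: pd.DataFrame,
    cluster_metrics: pd.DataFrame,
    fds_records: Sequence[FdsRecord] = (),
    covariates: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Join scoring, clustering, FDS, and covariate inputs into one table.

    Inputs are keyed by ``participant_id`` (+ ``condition`` where relevant);
    the result is a full outer join with one row per participant × condition
    × mode and explicit NaN for missing cells.  Conflicting duplicate keys
    are rejected by name.
    """
    for frame, keys, label in (
        (condition_scores, ["participant_id", "condition"], "condition_scores"),
        (cluster_metrics, ["participant_id", "condition", "mode"], "cluster_metrics"),
    ):
        if not frame.empty and frame.duplicated(subset=keys).any():
            dupes = frame.loc[frame.duplicated(subset=keys), keys]
            raise ValueError(f"duplicate keys in {label}: {dupes.to_dict('records')}")

    table = cluster_metrics.merge(
        condition_scores, on=["participant_id", "condition"], how="outer"
    )

    if fds_records:
        fds_frame = pd.DataFrame(
            [
                {
                    "participant_id": r.participant_id,
                    "condition": f"NS-{r.language}",
                    "fds": r.fds,
                }
                for r in fds_records
            ]
        )
        table = table.merge(fds_frame, on=["participant_id", "condition"], how="outer")
    else:
        table["fds"] = math.nan

    if covariates is not None:
        if covariates.duplicated(subset=["participant_id"]).any():
            raise ValueError("duplicate participant_id in covariates")
        table = table.merge(covariates, on="participant_id", how="left")

    sort_cols = [c for c in ("participant_id", "condition", "mode") if c in table]
    return table.sort_values(sort_cols).reset_index(drop=True)


def write_analysis_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the table as CSV with a machine-readable column dictionary."""
    path = Path(path)
    table.to_csv(path, index=False)
    sidecar = {c: COLUMN_DICTIONARY.get(c, "covariate column") for c in table.columns}
    path.with_suffix(".columns.json").write_text(
        json.dumps(sidecar, indent=2) + "\n", encoding="utf-8"
    )
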