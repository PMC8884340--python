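"""End-to-end glue: transcripts -> scored trials -> per-condition metrics
-> analysis table."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from bifluent.clusters import cluster_metrics, partition_responses
from bifluent.fluency import build_analysis_table, build_fds_records
from bifluent.lexicon import Lexicon
from bifluent.scoring import (
    LETTER_CONDITIONS,
    RawResponse,
    ScoringConfig,
    TrialScore,
    score_trial,
)

__all__ = ["PipelineResult", "rows_to_responses", "score_transcripts"]


@dataclass
class PipelineResult:
    trial_scores: list[TrialScore]
    trial_table: pd.DataFrame  # one row per trial x mode
    condition_scores: pd.DataFrame  # participant x condition mean_correct
    condition_metrics: pd.DataFrame  # participant x condition x mode averages
    analysis_table: pd.DataFrame
    scored_rows: pd.DataFrame  # per-response statuses


def rows_to_responses(frame: pd.DataFrame) -> list[RawResponse]:
    """Convert a transcript table (the TSV dialect) into responses."""
    responses = []
    for row in frame.itertuples(index=False):
        phonemes = getattr(row, "phonemes", "")
        if isinstance(phonemes, float):  # NaN from pandas
            phonemes = ""
        responses.append(
            RawResponse(
                participant_id=str(row.participant_id),
                group=str(row.group),
                task=str(row.task),
                condition=str(row.condition),
                target=str(row.target),
                administration=int(row.administration),
                position=int(row.position),
                token=str(row.token),
                produced_language=str(row.produced_language),
                phonemes=tuple(phonemes.split()) if phonemes else None,
            )
        )
    return responses


def _trial_groups(frame: pd.DataFrame):
    keys = ["participant_id", "condition", "target", "administration"]
    for _, trial_frame in frame.groupby(keys, sort=True):
        yield trial_frame.sort_values("position")


def score_transcripts(
    transcripts: pd.DataFrame,
    lexicon: Lexicon,
    l1_of: Mapping[str, str] | str,
    config: ScoringConfig = ScoringConfig(),
    lf_aggregate: str = "mean",
    cluster_rule: str = "pairwise",
) -> PipelineResult:
    """Score every trial in a transcript table and assemble all outputs.

    ``l1_of`` maps participant id to the first-acquired language, or is a
    single language tag applied to everyone.  Letter-fluency conditions are
    aggregated over their letters by mean (default) or sum before entering
    condition scores and FDS; cluster metrics are averaged over
    administrations (and letters).
    """
    if lf_aggregate not in ("mean", "sum"):
        raise ValueError("lf_aggregate must be 'mean' or 'sum'")

    trial_scores: list[TrialScore] = []
    trial_rows: list[dict] = []
    response_rows: list[dict] = []
    group_of: dict[str, str] = {}

    for trial_frame in _trial_groups(transcripts):
        responses = rows_to_responses(trial_frame)
        pid = responses[0].participant_id
        group_of[pid] = responses[0].group
        l1 = l1_of if isinstance(l1_of, str) else l1_of[pid]
        score = score_trial(responses, lexicon, l1=l1, config=config)
        trial_scores.append(score)

        mode = "phonemic" if score.condition in LETTER_CONDITIONS else "semantic"
        part = partition_responses(
            score.responses, mode, lexicon.inventory, cluster_rule=cluster_rule
        )
        if part.clusters:
            metrics = cluster_metrics(part)
            mcs, nsw = metrics.mean_cluster_size, metrics.n_switches
        else:
            mcs, nsw = np.nan, np.nan
        trial_rows.append(
            {
                "participant_id": pid,
                "group": responses[0].group,
                "condition": score.condition,
                "target": score.target,
                "administration": score.administration,
                "mode": mode,
                "n_correct": score.correct_count,
                "mean_cluster_size": mcs,
                "n_switches": nsw,
            }
        )
        for scored in score.responses:
            response_rows.append(
                {
                    "participant_id": pid,
                    "condition": score.condition,
                    "target": score.target,
                    "administration": score.administration,
                    "position": scored.raw.position,
                    "token": scored.raw.token,
                    "produced_language": scored.raw.produced_language,
                    "status": scored.status,
                    "matched_concept": (
                        scored.matched_entry.concept_id
                        if scored.matched_entry
                        else ""
                    ),
                    "edit_distance": (
                        scored.edit_distance_used
                        if scored.edit_distance_used is not None
                        else ""
                    ),
                }
            )

    trial_table = pd.DataFrame(trial_rows)
    if trial_table.empty:
        empty = pd.DataFrame()
        return PipelineResult([], trial_table, empty, empty, empty, pd.DataFrame())

    # condition-level correct counts: average letters within a condition,
    # then average administrations
    lf_agg = "mean" if lf_aggregate == "mean" else "sum"
    per_admin = (
        trial_table.groupby(
            ["participant_id", "condition", "administration"], as_index=False
        )
        .agg(
            n_correct=("n_correct", lf_agg),
            mean_cluster_size=("mean_cluster_size", "mean"),
            n_switches=("n_switches", "mean"),
            mode=("mode", "first"),
        )
    )
    n_admin = per_admin.groupby(["participant_id", "condition"])[
        "administration"
    ].count()
    condition_scores = (
        per_admin.groupby(["participant_id", "condition"], as_index=False)
        .agg(mean_correct=("n_correct", "mean"))
    )
    condition_scores["incomplete"] = [
        n_admin[(r.participant_id, r.condition)] < 2
        and r.condition not in LETTER_CONDITIONS
        for r in condition_scores.itertuples()
    ]

    condition_metrics = (
        per_admin.groupby(["participant_id", "condition", "mode"], as_index=False)
        .agg(
            mean_cluster_size=("mean_cluster_size", "mean"),
            n_switches=("n_switches", "mean"),
        )
    )

    fds_input = {
        (r.participant_id, r.condition): r.mean_correct
        for r in condition_scores.itertuples()
    }
    fds_records = build_fds_records(fds_input)

    table = build_analysis_table(
        condition_scores.drop(columns=["incomplete"]),
        condition_metrics,
        fds_records,
    )
    table.insert(1, "group", table["participant_id"].map(group_of))

    return PipelineResult(
        trial_scores=trial_scores,
        trial_table=trial_table,
        condition_scores=condition_scores,
        condition_metrics=condition_metrics,
        analysis_table=table,
        scored_rows=pd.DataFrame(response_rows),
    )
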