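"""Synthetic bilingual cohort generator.

Produces participants (covariates + questionnaire metrics + assessment
scores) and raw fluency transcripts with the group/condition structure the
analysis pipeline expects, so every downstream stage is testable without
participant data.

The word-production mechanism is a two-level Markov process: retrieval
attempts arrive Poisson; within an attempt the speaker either continues the
current subcategory (probability ``p_continue``) or tries to switch to a new
one (succeeding with ``p_switch_success``; a failed switch emits nothing).
Condition difficulty is encoded through ``p_switch_success`` and the
language-error rate only; ``lambda_items`` and ``p_continue`` are held
constant across the category conditions of a group.  The packaged default
spec is calibrated so group × condition mean correct counts approximate the
reference values in ``data/cohort_default.yaml``.

The generator is a statistical test harness, not a model of aphasia.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from bifluent.lexicon import LexicalEntry, Lexicon, load_lexicon
from bifluent.scoring import (
    CATEGORY_CONDITIONS,
    LETTER_CONDITIONS,
    RawResponse,
    required_language,
)

__all__ = [
    "ConditionParams",
    "LuqMetricSpec",
    "LuqStructure",
    "AssessmentSpec",
    "GroupSpec",
    "CohortSpec",
    "default_lexicon",
    "default_cohort_spec",
    "load_cohort_spec",
    "generate_luq",
    "generate_trial",
    "generate_cohort",
]

CATEGORIES = ("animals", "clothing", "food", "transportation")
LETTERS = {"english": ("f", "a", "s"), "spanish": ("p", "m", "r")}


def default_lexicon() -> Lexicon:
    """The packaged English/Spanish fixture lexicon."""
    path = resources.files("bifluent.data").joinpath("lexicon_en_es.tsv")
    return load_lexicon(Path(str(path)))


# ---------------------------------------------------------------------------
# Spec dataclasses


@dataclass(frozen=True)
class ConditionParams:
    lambda_items: float
    p_continue: float
    p_switch_success: float
    p_language_error: float = 0.0
    p_intrusion: float = 0.0
    p_repetition: float = 0.0
    p_paraphasia: float = 0.0

    def validate(self, label: str) -> list[str]:
        problems = []
        if self.lambda_items <= 0:
            problems.append(f"{label}: lambda_items must be > 0")
        for name in (
            "p_continue",
            "p_switch_success",
            "p_language_error",
            "p_intrusion",
            "p_repetition",
            "p_paraphasia",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                problems.append(f"{label}: {name}={value} outside [0, 1]")
        if self.p_intrusion + self.p_repetition + self.p_paraphasia > 1.0:
            problems.append(f"{label}: error rates sum above 1")
        return problems


@dataclass(frozen=True)
class LuqMetricSpec:
    loadings: tuple[float, ...]
    mean: float
    sd: float
    lower: float = 0.0
    upper: float = 100.0


@dataclass(frozen=True)
class LuqStructure:
    n_factors: int
    metrics: dict[str, LuqMetricSpec]

    def validate(self, label: str) -> list[str]:
        problems = []
        for name, spec in self.metrics.items():
            if len(spec.loadings) != self.n_factors:
                problems.append(
                    f"{label}.{name}: {len(spec.loadings)} loadings for "
                    f"{self.n_factors} factors"
                )
            if sum(l * l for l in spec.loadings) > 1.0:
                problems.append(f"{label}.{name}: communality above 1")
        return problems


@dataclass(frozen=True)
class AssessmentSpec:
    mean: float
    sd: float
    ability_loading: float


@dataclass(frozen=True)
class GroupSpec:
    n: int
    p_l1_spanish: float
    ability_sd: float
    ability_lambda_beta: float
    ability_switch_beta: float
    p_l1_in_self_switch: float
    conditions: dict[str, ConditionParams]
    luq: dict[str, LuqStructure]  # keyed "L1" / "L2"
    assessments: dict[str, AssessmentSpec]

    def validate(self, label: str) -> list[str]:
        problems = []
        if self.n < 0:
            problems.append(f"{label}: n must be >= 0")
        if not 0 <= self.p_l1_spanish <= 1:
            problems.append(f"{label}: p_l1_spanish outside [0, 1]")
        if not 0 <= self.p_l1_in_self_switch <= 1:
            problems.append(f"{label}: p_l1_in_self_switch outside [0, 1]")
        missing = set(CATEGORY_CONDITIONS + LETTER_CONDITIONS) - set(self.conditions)
        if missing:
            problems.append(f"{label}: missing condition params for {sorted(missing)}")
        for cond, params in self.conditions.items():
            problems.extend(params.validate(f"{label}.{cond}"))
        for slot, structure in self.luq.items():
            problems.extend(structure.validate(f"{label}.luq.{slot}"))
        return problems


@dataclass(frozen=True)
class CohortSpec:
    groups: dict[str, GroupSpec]

    def validate(self) -> None:
        problems = []
        for name, group in self.groups.items():
            problems.extend(group.validate(name))
        if problems:
            raise ValueError("invalid cohort spec:\n" + "\n".join(problems))


def _condition_from_dict(d: dict) -> ConditionParams:
    return ConditionParams(**d)


def _luq_from_dict(d: dict) -> LuqStructure:
    return LuqStructure(
        n_factors=d["n_factors"],
        metrics={
            name: LuqMetricSpec(
                loadings=tuple(m["loadings"]),
                mean=m["mean"],
                sd=m["sd"],
                lower=m.get("lower", 0.0),
                upper=m.get("upper", 100.0),
            )
            for name, m in d["metrics"].items()
        },
    )


def load_cohort_spec(path: str | Path) -> CohortSpec:
    """Read a cohort spec from YAML and validate it."""
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    groups = {}
    for name, g in payload["groups"].items():
        groups[name] = GroupSpec(
            n=g["n"],
            p_l1_spanish=g["p_l1_spanish"],
            ability_sd=g["ability_sd"],
            ability_lambda_beta=g["ability_lambda_beta"],
            ability_switch_beta=g["ability_switch_beta"],
            p_l1_in_self_switch=g["p_l1_in_self_switch"],
            conditions={
                cond: _condition_from_dict(params)
                for cond, params in g["conditions"].items()
            },
            luq={slot: _luq_from_dict(s) for slot, s in g["luq"].items()},
            assessments={
                name: AssessmentSpec(**a) for name, a in g["assessments"].items()
            },
        )
    spec = CohortSpec(groups=groups)
    spec.validate()
    return spec


def default_cohort_spec() -> CohortSpec:
    """The packaged spec, calibrated to the reference group × condition means."""
    path = resources.files("bifluent.data").joinpath("cohort_default.yaml")
    return load_cohort_spec(Path(str(path)))


# ---------------------------------------------------------------------------
# Questionnaire metrics


def generate_luq(
    structure: LuqStructure, rng: np.random.Generator, n: int
) -> pd.DataFrame:
    """Sample questionnaire metrics from a linear latent-factor model.

    Each metric is ``loadings . factors + residual`` on the z scale (unit
    variance: the residual SD is ``sqrt(1 - communality)``), then rescaled to
    its instrument range and clipped.
    """
    factors = rng.standard_normal((n, structure.n_factors))
    data = {}
    for name, spec in structure.metrics.items():
        loadings = np.asarray(spec.loadings)
        resid_sd = math.sqrt(max(0.0, 1.0 - float(loadings @ loadings)))
        z = factors @ loadings + resid_sd * rng.standard_normal(n)
        data[name] = np.clip(spec.mean + spec.sd * z, spec.lower, spec.upper)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Trial generation


def _logit_shift(p: float, shift: float) -> float:
    p = min(max(p, 1e-6), 1 - 1e-6)
    return 1.0 / (1.0 + math.exp(-(math.log(p / (1 - p)) + shift)))


class _Pool:
    """Unused words of one language for one target, grouped by 'subcategory'
    (semantic tag, or first-two-phoneme prefix in the letter task)."""

    def __init__(self, entries: list[LexicalEntry], task: str):
        self.groups: dict[str, list[LexicalEntry]] = {}
        for entry in entries:
            if task == "category":
                tags = sorted(entry.subcategories)
            else:
                tags = [" ".join(entry.phonemes[:2])]
            for tag in tags:
                self.groups.setdefault(tag, []).append(entry)
        for members in self.groups.values():
            members.sort(key=lambda e: e.form)
        self.used: set[str] = set()

    def unused(self, tag: str) -> list[LexicalEntry]:
        return [e for e in self.groups.get(tag, []) if e.form not in self.used]

    def tags_with_unused(self, exclude: Optional[str] = None) -> list[str]:
        return [
            t
            for t in sorted(self.groups)
            if t != exclude and self.unused(t)
        ]

    def take(self, entry: LexicalEntry) -> None:
        self.used.add(entry.form)


def _corrupt(
    entry: LexicalEntry, lexicon: Lexicon, rng: np.random.Generator
) -> tuple[str, tuple[str, ...]]:
    """Distort a word by two phoneme substitutions; invent a non-lexicon
    orthography for the transcript token."""
    symbols = sorted(lexicon.inventory.symbols)
    phonemes = list(entry.phonemes)
    positions = rng.permutation(len(phonemes))[: min(2, len(phonemes))]
    for i in positions:
        alternatives = [s for s in symbols if s != phonemes[i]]
        phonemes[i] = alternatives[rng.integers(len(alternatives))]
    token = entry.form + "~"
    while lexicon.lookup(token, entry.language) is not None:
        token += "~"
    return token, tuple(phonemes)


def generate_trial(
    params: ConditionParams,
    condition: str,
    target: str,
    lexicon: Lexicon,
    rng: np.random.Generator,
    l1: str,
    l2: str,
    participant_id: str = "P0",
    group: str = "SIM",
    administration: int = 1,
    p_l1_in_self_switch: float = 0.6,
) -> list[RawResponse]:
    """Simulate one trial of retrieval attempts and emissions.

    Returns transcript rows valid as scoring input.  Paraphasic productions
    carry a phoneme column (they are not lexicon forms); all other error
    types reuse real words.
    """
    task = "letter" if condition in LETTER_CONDITIONS else "category"
    lang_of_slot = {"L1": l1, "L2": l2}
    other = {l1: l2, l2: l1}

    pools = {}
    for lang in (l1, l2):
        if task == "category":
            entries = lexicon.in_category(target, lang)
        else:
            entries = lexicon.with_initial_letter(target, lang)
        pools[lang] = _Pool(entries, task)

    if task == "category":
        off_target = {
            lang: [
                e
                for e in lexicon
                if e.language == lang and e.category not in (None, target)
            ]
            for lang in (l1, l2)
        }
    else:
        off_target = {
            lang: [
                e
                for e in lexicon
                if e.language == lang and e.initial_letter != target
            ]
            for lang in (l1, l2)
        }
    for entries in off_target.values():
        entries.sort(key=lambda e: e.form)

    responses: list[RawResponse] = []
    emitted: list[tuple[str, str]] = []  # (form, language), for repetitions
    current_tag: Optional[str] = None
    attempts = int(rng.poisson(params.lambda_items))
    position = 1

    def emit(token: str, language: str, phonemes=None) -> None:
        nonlocal position
        responses.append(
            RawResponse(
                participant_id=participant_id,
                group=group,
                task=task,
                condition=condition,
                target=target,
                administration=administration,
                position=position,
                token=token,
                produced_language=language,
                phonemes=phonemes,
            )
        )
        emitted.append((token, language))
        position += 1

    for _ in range(attempts):
        slot = required_language(condition, position, "L1")
        if slot == "any":
            language = l1 if rng.random() < p_l1_in_self_switch else l2
        else:
            language = lang_of_slot[slot]
            # One-off deviation from the schedule.  The first forced-switch
            # emission is exempt: it anchors the alternation downstream.
            if not (condition == "FS" and position == 1):
                if rng.random() < params.p_language_error:
                    language = other[language]

        u = rng.random()
        if u < params.p_intrusion:
            candidates = off_target[language]
            if candidates:
                entry = candidates[rng.integers(len(candidates))]
                emit(entry.form, language)
            continue
        u -= params.p_intrusion
        if u < params.p_repetition:
            if emitted:
                token, lang_used = emitted[rng.integers(len(emitted))]
                emit(token, lang_used)
            continue
        u -= params.p_repetition
        paraphasia = u < params.p_paraphasia

        pool = pools[language]
        candidates = pool.unused(current_tag) if current_tag else []
        if not candidates or rng.random() >= params.p_continue:
            # switch attempt (forced when the running subcategory is spent)
            if rng.random() >= params.p_switch_success:
                continue
            tags = pool.tags_with_unused(exclude=current_tag)
            if not tags:
                if emitted:  # exhausted pool: fall back to a repetition
                    token, lang_used = emitted[rng.integers(len(emitted))]
                    emit(token, lang_used)
                continue
            current_tag = tags[rng.integers(len(tags))]
            candidates = pool.unused(current_tag)
        entry = candidates[rng.integers(len(candidates))]
        pool.take(entry)
        if paraphasia:
            token, phonemes = _corrupt(entry, lexicon, rng)
            emit(token, language, phonemes)
        else:
            emit(entry.form, language)

    return responses


# ---------------------------------------------------------------------------
# Full cohort


def _participant_conditions(
    group_spec: GroupSpec, ability: float
) -> dict[str, ConditionParams]:
    """Ability-adjusted condition parameters for one participant."""
    adjusted = {}
    lam_scale = math.exp(group_spec.ability_lambda_beta * ability)
    for cond, params in group_spec.conditions.items():
        adjusted[cond] = ConditionParams(
            lambda_items=params.lambda_items * lam_scale,
            p_continue=params.p_continue,
            p_switch_success=_logit_shift(
                params.p_switch_success, group_spec.ability_switch_beta * ability
            ),
            p_language_error=params.p_language_error,
            p_intrusion=params.p_intrusion,
            p_repetition=params.p_repetition,
            p_paraphasia=params.p_paraphasia,
        )
    return adjusted


def generate_cohort(
    spec: CohortSpec,
    seed: int,
    lexicon: Optional[Lexicon] = None,
    conditions: Optional[list[str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (participants, transcripts) for the full study design.

    Every participant receives four category conditions × two
    administrations (category-to-condition assignment shuffled per
    participant per administration) and three letter trials per language.
    Fully deterministic under a fixed seed.  ``conditions`` restricts the
    trial design (useful for fast simulation studies).
    """
    spec.validate()
    if lexicon is None:
        lexicon = default_lexicon()
    rng = np.random.default_rng(seed)
    wanted = set(conditions) if conditions is not None else None

    participants: list[dict] = []
    transcript_rows: list[dict] = []

    for group_name in sorted(spec.groups):
        group_spec = spec.groups[group_name]
        luq_samples = {
            slot: generate_luq(structure, rng, group_spec.n)
            for slot, structure in sorted(group_spec.luq.items())
        }
        for i in range(group_spec.n):
            pid = f"{group_name}{i + 1:03d}"
            l1 = "spanish" if rng.random() < group_spec.p_l1_spanish else "english"
            l2 = "english" if l1 == "spanish" else "spanish"
            ability = float(rng.standard_normal() * group_spec.ability_sd)

            record = {
                "participant_id": pid,
                "group": group_name,
                "l1": l1,
                "l2": l2,
                "ability": ability,
            }
            for slot, frame in luq_samples.items():
                for metric in frame.columns:
                    record[f"{slot.lower()}_{metric}"] = float(frame.iloc[i][metric])
            for name, assess in sorted(group_spec.assessments.items()):
                w = assess.ability_loading
                z = w * ability + math.sqrt(max(0.0, 1 - w * w)) * rng.standard_normal()
                record[name] = float(np.clip(assess.mean + assess.sd * z, 0, 100))
            participants.append(record)

            cond_params = _participant_conditions(group_spec, ability)
            for administration in (1, 2):
                assignment = rng.permutation(len(CATEGORIES))
                for cond, cat_index in zip(CATEGORY_CONDITIONS, assignment):
                    if wanted is not None and cond not in wanted:
                        continue
                    trial = generate_trial(
                        cond_params[cond],
                        cond,
                        CATEGORIES[cat_index],
                        lexicon,
                        rng,
                        l1,
                        l2,
                        participant_id=pid,
                        group=group_name,
                        administration=administration,
                        p_l1_in_self_switch=group_spec.p_l1_in_self_switch,
                    )
                    transcript_rows.extend(_to_rows(trial))
            for cond, slot in (("LF-L1", l1), ("LF-L2", l2)):
                if wanted is not None and cond not in wanted:
                    continue
                for letter in LETTERS[slot]:
                    trial = generate_trial(
                        cond_params[cond],
                        cond,
                        letter,
                        lexicon,
                        rng,
                        l1,
                        l2,
                        participant_id=pid,
                        group=group_name,
                        administration=1,
                    )
                    transcript_rows.extend(_to_rows(trial))

    participants_frame = pd.DataFrame(participants)
    columns = [
        "participant_id",
        "group",
        "task",
        "condition",
        "target",
        "administration",
        "position",
        "token",
        "produced_language",
        "phonemes",
    ]
    transcripts_frame = pd.DataFrame(transcript_rows, columns=columns)
    return participants_frame, transcripts_frame


def _to_rows(trial: list[RawResponse]) -> list[dict]:
    return [
        {
            "participant_id": r.participant_id,
            "group": r.group,
            "task": r.task,
            "condition": r.condition,
            "target": r.target,
            "administration": r.administration,
            "position": r.position,
            "token": r.token,
            "produced_language": r.produced_language,
            "phonemes": " ".join(r.phonemes) if r.phonemes else "",
        }
        for r in trial
    ]
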