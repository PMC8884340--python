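"""Condition-aware correctness scoring for fluency transcripts.

A response is correct when it is a unique word in the target category (or
begins with the target letter), is produced in the language the condition
requires at that position, is not a repetition within the trial, and is
within one phoneme substitution, omission, or addition of a lexicon word.
Error and repetition responses keep their place in the sequence: downstream
cluster/switch analyses include them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from bifluent.lexicon import LexicalEntry, Lexicon, normalize_form

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORY_CONDITIONS",
    "LETTER_CONDITIONS",
    "RawResponse",
    "ScoredResponse",
    "TrialScore",
    "ConditionScore",
    "ScoringConfig",
    "Target",
    "phoneme_edit_distance",
    "match_with_tolerance",
    "required_language",
    "score_trial",
    "average_administrations",
]

CATEGORY_CONDITIONS = ("NS-L1", "NS-L2", "SS", "FS")
LETTER_CONDITIONS = ("LF-L1", "LF-L2")

STATUSES = (
    "correct",
    "repetition",
    "category_error",
    "letter_error",
    "language_error",
    "form_error",
    "unknown",
)


@dataclass(frozen=True)
class RawResponse:
    """One produced token, as transcribed."""

    participant_id: str
    group: str
    task: str  # "category" | "letter"
    condition: str
    target: str  # category name or letter
    administration: int
    position: int
    token: str
    produced_language: str
    phonemes: Optional[tuple[str, ...]] = None  # for out-of-lexicon tokens

    def __post_init__(self) -> None:
        if self.task not in ("category", "letter"):
            raise ValueError(f"unknown task {self.task!r}")
        expected_task = "letter" if self.condition in LETTER_CONDITIONS else "category"
        if self.condition in CATEGORY_CONDITIONS + LETTER_CONDITIONS:
            if self.task != expected_task:
                raise ValueError(
                    f"task {self.task!r} inconsistent with condition {self.condition!r}"
                )
        if self.administration not in (1, 2):
            raise ValueError("administration must be 1 or 2")
        if self.position < 1:
            raise ValueError("position must be >= 1")


@dataclass(frozen=True)
class ScoredResponse:
    raw: RawResponse
    status: str
    matched_entry: Optional[LexicalEntry] = None
    edit_distance_used: Optional[int] = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "correct":
            assert self.matched_entry is not None
            assert self.edit_distance_used is not None and self.edit_distance_used <= 1


@dataclass(frozen=True)
class TrialScore:
    participant_id: str
    condition: str
    target: str
    administration: int
    responses: tuple[ScoredResponse, ...]
    correct_count: int

    def __post_init__(self) -> None:
        n = sum(1 for r in self.responses if r.status == "correct")
        if n != self.correct_count:
            raise ValueError("correct_count inconsistent with responses")


@dataclass(frozen=True)
class ConditionScore:
    participant_id: str
    condition: str
    mean_correct: float
    complete: bool = True  # False when only one administration was available


@dataclass(frozen=True)
class ScoringConfig:
    """Scoring policy knobs.

    ``concept_repetition``: when True, producing the translation equivalent
    of an earlier response counts as a repetition; default is word-form-level
    uniqueness, so translation equivalents are correct.
    """

    concept_repetition: bool = False


@dataclass(frozen=True)
class Target:
    """What a trial asks for: a semantic category or an initial letter."""

    kind: str  # "category" | "letter"
    value: str

    def __post_init__(self) -> None:
        if self.kind not in ("category", "letter"):
            raise ValueError(f"unknown target kind {self.kind!r}")
        object.__setattr__(self, "value", normalize_form(self.value))

    def admits(self, entry: LexicalEntry) -> bool:
        if self.kind == "category":
            return entry.category == self.value
        return entry.initial_letter == self.value


def phoneme_edit_distance(a: Sequence[str], b: Sequence[str]) -> int:
    """Levenshtein distance over phoneme labels, unit costs."""
    if len(a) < len(b):
        a, b = b, a
    previous = list(range(len(b) + 1))
    for i, pa in enumerate(a, 1):
        current = [i]
        for j, pb in enumerate(b, 1):
            current.append(
                min(
                    previous[j] + 1,  # deletion
                    current[j - 1] + 1,  # insertion
                    previous[j - 1] + (pa != pb),  # substitution
                )
            )
        previous = current
    return previous[-1]


def match_with_tolerance(
    token: str,
    language: str,
    target: Target,
    lexicon: Lexicon,
    token_phonemes: Optional[Sequence[str]] = None,
) -> tuple[Optional[LexicalEntry], Optional[int]]:
    """Resolve a token to a lexical entry, allowing one phonemic error.

    Exact orthographic match wins (distance 0), whatever its category — the
    caller decides whether the entry satisfies the target.  Otherwise the
    token's phoneme sequence (from the transcript) is compared against
    in-target entries of the same language; a unique nearest entry at
    distance 1 is accepted.  Ties at the minimal distance are broken by
    lexicographic concept id and logged.  Returns ``(None, None)`` when the
    token is unresolvable (no exact match and no phonemes to compare).
    """
    exact = lexicon.lookup(token, language)
    if exact is not None:
        return exact, 0
    if token_phonemes is None:
        return None, None
    language = language.strip().lower()
    candidates = [
        e for e in lexicon if e.language == language and target.admits(e)
    ]
    if not candidates:
        return None, None
    scored = [
        (phoneme_edit_distance(token_phonemes, e.phonemes), e.concept_id, e)
        for e in candidates
    ]
    scored.sort(key=lambda t: (t[0], t[1], t[2].form))
    best_distance = scored[0][0]
    ties = [t for t in scored if t[0] == best_distance]
    if len(ties) > 1:
        logger.info(
            "ambiguous match for %r at distance %d: %s; keeping %r",
            token,
            best_distance,
            [t[2].form for t in ties],
            ties[0][2].form,
        )
    return ties[0][2], best_distance


def required_language(
    condition: str, position: int, start_language: str = "L1"
) -> str:
    """Language slot ("L1", "L2", or "any") a condition demands at a position.

    Single-language conditions pin the slot; the self-switch condition allows
    either language; the forced-switch condition alternates strictly from the
    start language after each response.
    """
    if position < 1:
        raise ValueError("position must be >= 1")
    if condition in ("NS-L1", "LF-L1"):
        return "L1"
    if condition in ("NS-L2", "LF-L2"):
        return "L2"
    if condition == "SS":
        return "any"
    if condition == "FS":
        if start_language not in ("L1", "L2"):
            raise ValueError(f"bad start_language {start_language!r}")
        other = "L2" if start_language == "L1" else "L1"
        return start_language if position % 2 == 1 else other
    raise ValueError(f"unknown condition {condition!r}")


def _trial_key(response: RawResponse) -> tuple:
    return (
        response.participant_id,
        response.condition,
        response.target,
        response.administration,
    )


def score_trial(
    responses: Sequence[RawResponse],
    lexicon: Lexicon,
    l1: str,
    l2: Optional[str] = None,
    config: ScoringConfig = ScoringConfig(),
) -> TrialScore:
    """Score one trial (one participant × condition × target × administration).

    ``l1``/``l2`` name the participant's first- and second-acquired languages
    concretely (e.g. ``"spanish"``/``"english"``); ``l2`` defaults to the
    other language present in the lexicon.  Statuses are assigned with the
    precedence: unknown, category/letter error, language error, repetition,
    form error, correct.  All responses are retained in order.
    """
    if not responses:
        raise ValueError("empty trial")
    keys = {_trial_key(r) for r in responses}
    if len(keys) > 1:
        raise ValueError(f"mixed trial input: {sorted(keys)}")
    positions = [r.position for r in sorted(responses, key=lambda r: r.position)]
    if positions != list(range(1, len(responses) + 1)):
        raise ValueError(f"positions not consecutive from 1: {positions}")
    responses = sorted(responses, key=lambda r: r.position)

    l1 = l1.strip().lower()
    if l2 is None:
        others = sorted(lexicon.languages - {l1})
        if len(others) != 1:
            raise ValueError("cannot infer l2; pass it explicitly")
        l2 = others[0]
    l2 = l2.strip().lower()
    lang_of_slot = {"L1": l1, "L2": l2}
    slot_of_lang = {l1: "L1", l2: "L2"}

    first = responses[0]
    target = Target(
        "letter" if first.task == "letter" else "category", first.target
    )
    # Forced-switch alternation is anchored at the first produced language.
    start_slot = slot_of_lang.get(first.produced_language.strip().lower(), "L1")

    produced_forms: set[tuple[str, str]] = set()
    produced_concepts: set[str] = set()
    scored: list[ScoredResponse] = []
    for response in responses:
        language = response.produced_language.strip().lower()
        entry, distance = match_with_tolerance(
            response.token, language, target, lexicon, response.phonemes
        )

        status = None
        if entry is None:
            status = "unknown"
        elif distance == 0 and not target.admits(entry):
            status = "category_error" if target.kind == "category" else "letter_error"
        if status is None:
            slot = required_language(response.condition, response.position, start_slot)
            if slot != "any" and lang_of_slot[slot] != language:
                status = "language_error"
        if status is None:
            form = normalize_form(response.token)
            if (form, language) in produced_forms:
                status = "repetition"
            elif config.concept_repetition and entry.concept_id in produced_concepts:
                status = "repetition"
        if status is None and distance is not None and distance > 1:
            status = "form_error"
        if status is None:
            status = "correct"

        produced_forms.add((normalize_form(response.token), language))
        if entry is not None:
            produced_concepts.add(entry.concept_id)
        scored.append(
            ScoredResponse(
                raw=response,
                status=status,
                matched_entry=entry,
                edit_distance_used=distance,
            )
        )

    return TrialScore(
        participant_id=first.participant_id,
        condition=first.condition,
        target=first.target,
        administration=first.administration,
        responses=tuple(scored),
        correct_count=sum(1 for r in scored if r.status == "correct"),
    )


def average_administrations(
    t1: TrialScore, t2: Optional[TrialScore] = None
) -> ConditionScore:
    """Average correct counts over the two administrations of a condition.

    With a single available administration the score is that count, flagged
    incomplete.
    """
    if t2 is None:
        return ConditionScore(
            participant_id=t1.participant_id,
            condition=t1.condition,
            mean_correct=float(t1.correct_count),
            complete=False,
        )
    if (t1.participant_id, t1.condition) != (t2.participant_id, t2.condition):
        raise ValueError("administrations from different participant/condition")
    return ConditionScore(
        participant_id=t1.participant_id,
        condition=t1.condition,
        mean_correct=(t1.correct_count + t2.correct_count) / 2.0,
    )
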