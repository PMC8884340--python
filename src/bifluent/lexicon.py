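"""Bilingual lexicon resources: phoneme inventories, entries, lookup.

The lexicon is a flat word store keyed by ``(form, language)``.  Entries that
belong to a semantic category carry one or more subcategory tags (the tag
taxonomy is data, shipped in the lexicon file, never code) and every entry
carries a phoneme sequence drawn from a declared per-file inventory.
Translation equivalents share a ``concept_id``.

File dialect (TSV)::

    #phonemes: a b ch d ...
    #vowels: a e i o u ...
    form<TAB>language<TAB>concept_id<TAB>category<TAB>subcategories<TAB>phonemes

``subcategories`` is ``;``-separated, ``phonemes`` space-separated, ``-`` marks
an absent category.  A JSON mirror with the same field names is accepted.
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "LexiconError",
    "PhonemeInventory",
    "LexicalEntry",
    "Lexicon",
    "normalize_form",
    "load_lexicon",
    "write_lexicon",
    "shared_subcategory",
]


class LexiconError(ValueError):
    """Raised when a lexicon file fails validation; message names the rows."""


def normalize_form(form: str) -> str:
    """Unicode NFC + lowercase; diacritics are preserved (Spanish minimal
    pairs depend on them)."""
    return unicodedata.normalize("NFC", form).strip().lower()


@dataclass(frozen=True)
class PhonemeInventory:
    """A set of phoneme labels partitioned into vowels and consonants."""

    symbols: frozenset[str]
    vowels: frozenset[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise LexiconError("phoneme inventory is empty")
        if not self.vowels <= self.symbols:
            extra = sorted(self.vowels - self.symbols)
            raise LexiconError(f"vowels not in inventory: {extra}")

    @property
    def consonants(self) -> frozenset[str]:
        return self.symbols - self.vowels

    def is_vowel(self, symbol: str) -> bool:
        if symbol not in self.symbols:
            raise LexiconError(f"unknown phoneme symbol: {symbol!r}")
        return symbol in self.vowels

    def validate_sequence(self, phonemes: Iterable[str]) -> tuple[str, ...]:
        seq = tuple(phonemes)
        if not seq:
            raise LexiconError("empty phoneme sequence")
        unknown = [p for p in seq if p not in self.symbols]
        if unknown:
            raise LexiconError(f"unknown phoneme symbol(s): {sorted(set(unknown))}")
        return seq


@dataclass(frozen=True)
class LexicalEntry:
    """One word in one language.

    ``category`` is ``None`` for letter-task words; category-bearing entries
    must carry at least one subcategory tag.
    """

    form: str
    language: str
    concept_id: str
    category: Optional[str]
    subcategories: frozenset[str]
    phonemes: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "form", normalize_form(self.form))
        object.__setattr__(self, "language", self.language.strip().lower())
        if self.category is not None and not self.subcategories:
            raise LexiconError(
                f"entry {self.form!r}/{self.language}: category-bearing entry "
                "has no subcategory tags"
            )
        if not self.phonemes:
            raise LexiconError(f"entry {self.form!r}/{self.language}: no phonemes")

    @property
    def initial_letter(self) -> str:
        return self.form[0]

    @property
    def key(self) -> tuple[str, str]:
        return (self.form, self.language)


class Lexicon:
    """Validated store of :class:`LexicalEntry`, with concept and phoneme
    indexes for exact and tolerance lookup."""

    def __init__(self, entries: Iterable[LexicalEntry], inventory: PhonemeInventory):
        self.inventory = inventory
        self._entries: dict[tuple[str, str], LexicalEntry] = {}
        self._by_concept: dict[str, list[LexicalEntry]] = {}
        for entry in entries:
            inventory.validate_sequence(entry.phonemes)
            if entry.key in self._entries:
                raise LexiconError(
                    f"duplicate (form, language): {entry.form!r}/{entry.language}"
                )
            self._entries[entry.key] = entry
            self._by_concept.setdefault(entry.concept_id, []).append(entry)
        if not self._entries:
            raise LexiconError("no entries")

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def lookup(self, token: str, language: str) -> Optional[LexicalEntry]:
        """Exact-match retrieval: case-insensitive, diacritic-sensitive.
        Absence is a value, never an error."""
        return self._entries.get((normalize_form(token), language.strip().lower()))

    def by_concept(self, concept_id: str) -> list[LexicalEntry]:
        return list(self._by_concept.get(concept_id, []))

    def translation(self, entry: LexicalEntry, language: str) -> Optional[LexicalEntry]:
        language = language.strip().lower()
        for candidate in self._by_concept.get(entry.concept_id, []):
            if candidate.language == language:
                return candidate
        return None

    @property
    def languages(self) -> frozenset[str]:
        return frozenset(e.language for e in self)

    @property
    def categories(self) -> frozenset[str]:
        return frozenset(e.category for e in self if e.category is not None)

    def in_category(self, category: str, language: str) -> list[LexicalEntry]:
        language = language.strip().lower()
        return [
            e
            for e in self
            if e.category == category and e.language == language
        ]

    def with_initial_letter(self, letter: str, language: str) -> list[LexicalEntry]:
        letter = normalize_form(letter)
        language = language.strip().lower()
        return [
            e
            for e in self
            if e.language == language and e.initial_letter == letter
        ]

    def validate_consistency(self) -> None:
        """Translation equivalents must agree on category and subcategory
        tags (linkage is concept-level)."""
        problems = []
        for concept_id, entries in self._by_concept.items():
            cats = {e.category for e in entries}
            tags = {e.subcategories for e in entries}
            if len(cats) > 1 or len(tags) > 1:
                problems.append(concept_id)
        if problems:
            raise LexiconError(
                f"concepts with inconsistent category/subcategories: {sorted(problems)}"
            )


def shared_subcategory(a: LexicalEntry, b: LexicalEntry) -> bool:
    """True iff the two entries share at least one subcategory tag.

    Comparison is concept-level and ignores the entries' languages; entries
    from different categories (or without a category) compare false, never
    raise.
    """
    if a.category is None or b.category is None or a.category != b.category:
        return False
    return bool(a.subcategories & b.subcategories)


# ---------------------------------------------------------------------------
# File I/O

_COLUMNS = ["form", "language", "concept_id", "category", "subcategories", "phonemes"]


def _parse_directives(lines: list[str]) -> tuple[Optional[PhonemeInventory], int]:
    symbols: Optional[list[str]] = None
    vowels: Optional[list[str]] = None
    n_header = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_header += 1
        body = line.lstrip("#").strip()
        if body.lower().startswith("phonemes:"):
            symbols = body.split(":", 1)[1].split()
        elif body.lower().startswith("vowels:"):
            vowels = body.split(":", 1)[1].split()
    if symbols is None:
        return None, n_header
    return (
        PhonemeInventory(frozenset(symbols), frozenset(vowels or [])),
        n_header,
    )


def _entry_from_record(record: dict, row: int) -> LexicalEntry:
    missing = [c for c in _COLUMNS if c not in record or record[c] in (None, "")]
    if missing:
        raise LexiconError(f"row {row}: missing field(s) {missing}")
    category = record["category"]
    if category in ("-", "none", "NA"):
        category = None
    subcats = record["subcategories"]
    if isinstance(subcats, str):
        subcats = [s for s in subcats.split(";") if s and s != "-"]
    phonemes = record["phonemes"]
    if isinstance(phonemes, str):
        phonemes = phonemes.split()
    try:
        return LexicalEntry(
            form=record["form"],
            language=record["language"],
            concept_id=str(record["concept_id"]),
            category=category,
            subcategories=frozenset(subcats),
            phonemes=tuple(phonemes),
        )
    except LexiconError as exc:
        raise LexiconError(f"row {row}: {exc}") from exc


def load_lexicon(
    path: str | Path, inventory: Optional[PhonemeInventory] = None
) -> Lexicon:
    """Load and validate a lexicon from TSV (or its JSON mirror).

    The phoneme inventory may be supplied explicitly or declared in
    ``#phonemes:`` / ``#vowels:`` header lines; an explicit argument wins.
    Malformed rows, unknown phoneme symbols, and duplicate (form, language)
    pairs abort the load with an error naming the offending rows.
    """
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        if inventory is None:
            inv = payload.get("inventory", {})
            if not inv:
                raise LexiconError(f"{path}: no phoneme inventory declared")
            inventory = PhonemeInventory(
                frozenset(inv["phonemes"]), frozenset(inv["vowels"])
            )
        records = payload["entries"]
        entries = [_entry_from_record(r, i + 1) for i, r in enumerate(records)]
    else:
        lines = path.read_text(encoding="utf-8").splitlines()
        declared, n_header = _parse_directives(lines)
        if inventory is None:
            inventory = declared
        if inventory is None:
            raise LexiconError(f"{path}: no phoneme inventory declared")
        entries = []
        data_lines = lines[n_header:]
        if data_lines and data_lines[0].split("\t")[0] == "form":
            start = n_header + 2
            data_lines = data_lines[1:]
        else:
            start = n_header + 1
        for offset, line in enumerate(data_lines):
            if not line.strip() or line.startswith("#"):
                continue
            row = start + offset
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(_COLUMNS):
                raise LexiconError(
                    f"row {row}: expected {len(_COLUMNS)} columns, got {len(cells)}"
                )
            entries.append(_entry_from_record(dict(zip(_COLUMNS, cells)), row))

    errors = []
    for i, entry in enumerate(entries, 1):
        unknown = [p for p in entry.phonemes if p not in inventory.symbols]
        if unknown:
            errors.append(
                f"row for {entry.form!r}/{entry.language}: unknown phoneme "
                f"symbol(s) {sorted(set(unknown))}"
            )
    if errors:
        raise LexiconError("; ".join(errors))

    lexicon = Lexicon(entries, inventory)
    lexicon.validate_consistency()
    return lexicon


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    """Write the TSV dialect read by :func:`load_lexicon` (round-trips)."""
    path = Path(path)
    lines = [
        "#phonemes: " + " ".join(sorted(lexicon.inventory.symbols)),
        "#vowels: " + " ".join(sorted(lexicon.inventory.vowels)),
        "\t".join(_COLUMNS),
    ]
    for entry in sorted(lexicon, key=lambda e: e.key):
        lines.append(
            "\t".join(
                [
                    entry.form,
                    entry.language,
                    entry.concept_id,
                    entry.category if entry.category is not None else "-",
                    ";".join(sorted(entry.subcategories)) or "-",
                    " ".join(entry.phonemes),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
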