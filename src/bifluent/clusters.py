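"""Cluster partitioning and switch counting for scored response sequences.

Semantic clusters are runs of consecutive words sharing a semantic
subcategory; phonemic clusters are runs where each consecutive pair begins
with the same first two sounds, differs only by vowel sounds, rhymes, or is a
homonym pair.  Cluster size counts from the second word (a singleton scores
0, a two-word cluster 1); mean cluster size divides the summed sizes by the
number of clusters; switches are transitions between clusters, singletons
included.  Errors and repetitions participate like any other production.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

from bifluent.lexicon import LexicalEntry, PhonemeInventory, shared_subcategory
from bifluent.scoring import ScoredResponse

__all__ = [
    "ClusterPartition",
    "ClusterMetrics",
    "semantic_link",
    "phonemic_link",
    "phonemic_link_criteria",
    "partition_responses",
    "partition_items",
    "cluster_metrics",
]


@dataclass(frozen=True)
class ClusterPartition:
    """Ordered, contiguous, non-overlapping clusters of response indices."""

    clusters: tuple[tuple[int, ...], ...]
    mode: str  # "semantic" | "phonemic"
    n_items: int

    def __post_init__(self) -> None:
        flattened = [i for cluster in self.clusters for i in cluster]
        if flattened != list(range(self.n_items)):
            raise ValueError("clusters must cover all items exactly once, in order")
        if any(len(c) == 0 for c in self.clusters):
            raise ValueError("empty cluster")

    @property
    def sizes(self) -> tuple[int, ...]:
        """Per-cluster size, counted from the second word (span length - 1)."""
        return tuple(len(c) - 1 for c in self.clusters)


@dataclass(frozen=True)
class ClusterMetrics:
    mean_cluster_size: float
    n_switches: int
    n_clusters: int


def semantic_link(a: Optional[LexicalEntry], b: Optional[LexicalEntry]) -> bool:
    """Concept-level subcategory sharing; unresolved items never link."""
    if a is None or b is None:
        return False
    return shared_subcategory(a, b)


def phonemic_link_criteria(
    a: Optional[LexicalEntry],
    b: Optional[LexicalEntry],
    inventory: PhonemeInventory,
) -> frozenset[str]:
    """Which phonemic clustering criteria hold between two words.

    Possible members: ``first_two`` (identical first two phonemes),
    ``vowel_only`` (same length, every mismatch vowel-for-vowel, at least
    one mismatch), ``rhyme`` (identical suffix from the final vowel onward),
    ``homonym`` (identical phoneme sequences under different spellings).
    Cross-language pairs never link: the criteria are only defined within
    one phoneme system.
    """
    if a is None or b is None or a.language != b.language:
        return frozenset()
    pa, pb = a.phonemes, b.phonemes
    hits = set()

    if len(pa) >= 2 and len(pb) >= 2 and pa[:2] == pb[:2]:
        hits.add("first_two")

    if len(pa) == len(pb):
        mismatches = [(x, y) for x, y in zip(pa, pb) if x != y]
        if mismatches and all(
            inventory.is_vowel(x) and inventory.is_vowel(y) for x, y in mismatches
        ):
            hits.add("vowel_only")

    sa, sb = _rhyme_suffix(pa, inventory), _rhyme_suffix(pb, inventory)
    if sa is not None and sa == sb:
        hits.add("rhyme")

    if pa == pb and a.form != b.form:
        hits.add("homonym")

    return frozenset(hits)


def phonemic_link(
    a: Optional[LexicalEntry],
    b: Optional[LexicalEntry],
    inventory: PhonemeInventory,
) -> bool:
    """True when any phonemic clustering criterion holds between two words."""
    return bool(phonemic_link_criteria(a, b, inventory))


def _rhyme_suffix(
    phonemes: Sequence[str], inventory: PhonemeInventory
) -> Optional[tuple[str, ...]]:
    for i in range(len(phonemes) - 1, -1, -1):
        if inventory.is_vowel(phonemes[i]):
            return tuple(phonemes[i:])
    return None


def partition_items(
    items: Sequence, link: Callable[[object, object], bool], mode: str = "semantic"
) -> ClusterPartition:
    """Greedy left-to-right chaining: a cluster extends while each consecutive
    pair satisfies ``link``; otherwise a new cluster starts."""
    clusters: list[list[int]] = []
    for i in range(len(items)):
        if clusters and link(items[clusters[-1][-1]], items[i]):
            clusters[-1].append(i)
        else:
            clusters.append([i])
    return ClusterPartition(
        clusters=tuple(tuple(c) for c in clusters), mode=mode, n_items=len(items)
    )


def partition_responses(
    responses: Sequence[ScoredResponse],
    mode: str,
    inventory: Optional[PhonemeInventory] = None,
    cluster_rule: str = "pairwise",
) -> ClusterPartition:
    """Partition a scored trial in semantic or phonemic mode.

    ``cluster_rule="pairwise"`` links each consecutive pair independently
    (the default; matches the worked scoring examples).  ``"common_tag"``
    (semantic mode only) additionally requires a subcategory tag common to
    the whole cluster so far.
    """
    if mode not in ("semantic", "phonemic"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "phonemic" and inventory is None:
        raise ValueError("phonemic mode requires a phoneme inventory")

    entries = [r.matched_entry for r in responses]

    if mode == "semantic" and cluster_rule == "common_tag":
        return _partition_common_tag(entries)

    if mode == "semantic":
        link = semantic_link
    else:
        link = lambda a, b: phonemic_link(a, b, inventory)  # noqa: E731
    return partition_items(entries, link, mode=mode)


def _partition_common_tag(entries: Sequence[Optional[LexicalEntry]]) -> ClusterPartition:
    clusters: list[list[int]] = []
    running_tags: frozenset[str] = frozenset()
    for i, entry in enumerate(entries):
        tags = entry.subcategories if entry is not None and entry.category else frozenset()
        if clusters and running_tags and tags & running_tags:
            clusters[-1].append(i)
            running_tags = running_tags & tags
        else:
            clusters.append([i])
            running_tags = tags
    return ClusterPartition(
        clusters=tuple(tuple(c) for c in clusters), mode="semantic", n_items=len(entries)
    )


def cluster_metrics(partition: ClusterPartition) -> ClusterMetrics:
    """Mean cluster size and switch count for a non-empty partition.

    Empty input has no defined metrics: raising keeps an absent trial from
    masquerading as a zero score.
    """
    n_clusters = len(partition.clusters)
    if n_clusters == 0:
        raise ValueError("metrics undefined for an empty partition")
    sizes = partition.sizes
    return ClusterMetrics(
        mean_cluster_size=sum(sizes) / n_clusters,
        n_switches=n_clusters - 1,
        n_clusters=n_clusters,
    )
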