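"""Collapse retailer name variants onto canonical entities.

Chains appear in listings under many spellings ("Kroger", "The Kroger
Company", "Kroger Co", "Bp Food Mart" vs "B P Food Mart").  Names are
lowercased, stripped of punctuation, and cleared of stop-words — both
ordinary ones ("the", "a", "'s") and *generic* retail tokens curated from a
token-frequency report ("supercenter", "mart", "store", "restaurant",
corporate suffixes and their variants).  Normalized names are then merged by
Ratcliff-Obershelp similarity

    d_ro = 2 * c_m / (|s1| + |s2|)

where c_m is the number of matching characters found by recursively removing
the longest matching substring.  Working shortest-to-longest, a name adopts
an already-assigned shorter canonical name when the similarity strictly
exceeds the threshold (default 0.8); otherwise it founds a new entity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

_DEFAULT_BASE_STOPWORDS = frozenset({"the", "a", "an", "of", "and", "s"})
# The generic list extends four canonical examples (supercenter, mart, store,
# restaurant) with their plural/spelling variants and corporate suffixes;
# it is a curated, user-extensible list, not auto-derived.
_DEFAULT_GENERIC_STOPWORDS = frozenset(
    {
        "supercenter",
        "supercenters",
        "mart",
        "marts",
        "store",
        "stores",
        "shop",
        "shoppe",
        "restaurant",
        "restaurants",
        "co",
        "company",
        "inc",
        "llc",
        "corp",
        "corporation",
    }
)


@dataclass(frozen=True)
class NameMatchConfig:
    similarity_threshold: float = 0.8
    base_stopwords: frozenset[str] = _DEFAULT_BASE_STOPWORDS
    generic_stopwords: frozenset[str] = _DEFAULT_GENERIC_STOPWORDS
    generic_top_k: int = 30

    def __post_init__(self) -> None:
        if not 0.0 < self.similarity_threshold <= 1.0:
            raise ValueError("similarity_threshold must lie in (0, 1]")


@dataclass
class CanonicalMap:
    """name → canonical name, plus per-entity occurrence counts."""

    mapping: dict[str, str] = field(default_factory=dict)
    entity_counts: Counter = field(default_factory=Counter)
    flagged: set[str] = field(default_factory=set)

    def canonical(self, name: str) -> str:
        return self.mapping[name]


def _tokenize(name: str) -> list[str]:
    cleaned = "".join(ch if ch.isalnum() else " " for ch in name.lower())
    return cleaned.split()


def normalize_flagged(name: str, config: NameMatchConfig | None = None) -> tuple[str, bool]:
    """Normalized name plus a flag marking the degenerate all-stop-words case."""
    config = config or NameMatchConfig()
    stop = config.base_stopwords | config.generic_stopwords
    tokens = [t for t in _tokenize(name) if t not in stop]
    if tokens:
        return " ".join(tokens), False
    # Everything was a stop-word: fall back to the lowercased original.
    return " ".join(_tokenize(name)) or name.strip().lower(), True


def normalize(name: str, config: NameMatchConfig | None = None) -> str:
    return normalize_flagged(name, config)[0]


def _longest_match(a: str, b: str) -> tuple[int, int, int]:
    """Longest common substring (i, j, size); ties go to the earliest start
    in ``a``, then the earliest start in ``b``."""
    besti = bestj = bestsize = 0
    prev: dict[int, int] = {}
    b_positions: dict[str, list[int]] = {}
    for j, ch in enumerate(b):
        b_positions.setdefault(ch, []).append(j)
    for i, ch in enumerate(a):
        cur: dict[int, int] = {}
        for j in b_positions.get(ch, ()):
            size = prev.get(j - 1, 0) + 1
            cur[j] = size
            if size > bestsize:
                besti, bestj, bestsize = i - size + 1, j - size + 1, size
        prev = cur
    return besti, bestj, bestsize


def _matching_chars(a: str, b: str) -> int:
    """c_m of the Ratcliff-Obershelp decomposition: recursively count the
    longest matching substring, then match what lies left of it on both
    sides and right of it on both sides."""
    if not a or not b:
        return 0
    i, j, size = _longest_match(a, b)
    if size == 0:
        return 0
    return (
        size
        + _matching_chars(a[:i], b[:j])
        + _matching_chars(a[i + size :], b[j + size :])
    )


def ro_similarity(s1: str, s2: str) -> float:
    """Ratcliff-Obershelp similarity: 2·c_m / (|s1| + |s2|), in [0, 1].

    The recursive longest-matching-substring decomposition is order
    dependent in rare tie cases, so the pair is put into a canonical order
    (shorter first, ties lexicographic) before matching; the measure is
    therefore symmetric by construction.
    """
    if not s1 and not s2:
        return 1.0
    a, b = sorted((s1, s2), key=lambda s: (len(s), s))
    return 2.0 * _matching_chars(a, b) / (len(a) + len(b))


def frequent_token_report(names: list[str], k: int) -> list[tuple[str, int]]:
    """Top-k tokens by frequency (ties lexicographic) across already-lowercased
    names; the human-curation input for the generic stop-word list."""
    counts = Counter(t for name in names for t in _tokenize(name))
    ranked = sorted(counts.items(), key=lambda tc: (-tc[1], tc[0]))
    return ranked[: max(k, 0)]


def canonicalize(names: list[str], config: NameMatchConfig | None = None) -> CanonicalMap:
    """Assign every name a canonical entity.

    Unique normalized names are processed in ascending length (ties
    lexicographic).  Each is compared against every canonical name assigned
    so far — all of which are no longer than it — and adopts the best match
    when similarity strictly exceeds the threshold, preferring higher
    similarity, then shorter, then lexicographically earlier candidates.
    Otherwise it becomes its own canonical entity.
    """
    config = config or NameMatchConfig()
    result = CanonicalMap()

    norm_of: dict[str, str] = {}
    occurrences: Counter = Counter()
    for name in names:
        norm, flagged = normalize_flagged(name, config)
        norm_of[name] = norm
        occurrences[norm] += 1
        if flagged:
            result.flagged.add(name)

    canonicals: list[str] = []
    canon_of_norm: dict[str, str] = {}
    for norm in sorted(occurrences, key=lambda s: (len(s), s)):
        best: tuple[float, int, str] | None = None
        for cand in canonicals:
            if len(cand) > len(norm):
                continue
            sim = ro_similarity(norm, cand)
            key = (-sim, len(cand), cand)
            if best is None or key < (-best[0], best[1], best[2]):
                best = (sim, len(cand), cand)
        if best is not None and best[0] > config.similarity_threshold:
            canon_of_norm[norm] = best[2]
        else:
            canon_of_norm[norm] = norm
            canonicals.append(norm)

    for name, norm in norm_of.items():
        result.mapping[name] = canon_of_norm[norm]
    for canon in canonicals:
        result.mapping.setdefault(canon, canon)
    for norm, n in occurrences.items():
        result.entity_counts[canon_of_norm[norm]] += n
    return result


def annotation_queue(canonical_map: CanonicalMap, min_count: int = 4) -> list[str]:
    """Canonical entities frequent enough to be worth a questionnaire.

    Entities appearing more than three times (count ≥ 4 by default) are
    queued, most frequent first.
    """
    eligible = [
        (n, c) for c, n in (
            (cnt, name) for name, cnt in canonical_map.entity_counts.items()
        ) if c >= min_count
    ]
    eligible.sort(key=lambda nc: (-nc[1], nc[0]))
    return [name for name, _ in eligible]


def top_matches_report(
    canonical_map: CanonicalMap, k: int = 100
) -> list[tuple[str, str, int]]:
    """(original name, canonical name, entity count) for the k busiest
    entities — the manual-inspection protocol for validating the matcher."""
    top = {
        name
        for name, _ in sorted(
            canonical_map.entity_counts.items(), key=lambda nc: (-nc[1], nc[0])
        )[:k]
    }
    rows = [
        (orig, canon, canonical_map.entity_counts[canon])
        for orig, canon in sorted(canonical_map.mapping.items())
        if canon in top
    ]
    rows.sort(key=lambda r: (-r[2], r[1], r[0]))
    return rows
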