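"""Questionnaire schemas, majority-vote consensus, and health classification.

Each canonical retailer entity frequent enough to matter is assessed by five
independent annotators with a shortened nutrition-environment questionnaire
(one schema for stores, one for restaurants).  Per question, the plurality
answer wins; an exact tie is recorded as "tie" and contributes "unknown"
downstream — it is never silently resolved.  The consensus retailer type
then fixes the binary health class by the CDC retail-food-environment
category rule: supermarkets, large grocery stores, supercenters, produce
stores (and farmers' markets) are healthy; fast-food restaurants, small
grocery stores and convenience stores are less healthy; everything else is
unknown.  Entities too rare to be surveyed fall back to listing-tag
keywords.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

TIE = "tie"

STORE_QUESTIONS = (
    "retailer_type",
    "fresh_produce_available",
    "whole_grains_available",
    "low_fat_dairy_available",
    "prepared_healthy_options",
)
RESTAURANT_QUESTIONS = (
    "venue_type",
    "healthy_mains_offered",
    "fried_food_dominant",
    "fresh_vegetables_offered",
)
SCHEMAS: dict[str, tuple[str, ...]] = {
    "store": STORE_QUESTIONS,
    "restaurant": RESTAURANT_QUESTIONS,
}

RETAILER_TYPES = (
    "supermarket",
    "large_grocery",
    "supercenter",
    "produce_store",
    "small_grocery",
    "convenience",
    "fast_food",
    "restaurant_other",
    "deli",
    "farmers_market",
    "unknown",
)

HEALTHY_TYPES = frozenset(
    {"supermarket", "large_grocery", "supercenter", "produce_store", "farmers_market"}
)
LESS_HEALTHY_TYPES = frozenset({"fast_food", "small_grocery", "convenience"})

#: Listing-tag keyword → retailer type, used for entities with no consensus.
DEFAULT_TAG_TYPE_MAP: dict[str, str] = {
    "supermarket": "supermarket",
    "supermarkets": "supermarket",
    "grocery": "large_grocery",
    "organic_store": "produce_store",
    "healthmarkets": "produce_store",
    "farmers_market": "farmers_market",
    "supercenter": "supercenter",
    "convenience_store": "convenience",
    "convenience": "convenience",
    "fast_food": "fast_food",
    "fastfood": "fast_food",
    "small_grocery": "small_grocery",
    "deli": "deli",
    "delis": "deli",
    "restaurant": "restaurant_other",
    "restaurants": "restaurant_other",
}


@dataclass(frozen=True)
class QuestionnaireResponse:
    canonical_name: str
    annotator_id: str
    venue_kind: str  # store | restaurant
    answers: tuple[str, ...]

    def __post_init__(self) -> None:
        schema = SCHEMAS.get(self.venue_kind)
        if schema is None:
            raise ValueError(f"unknown venue_kind {self.venue_kind!r}")
        if len(self.answers) != len(schema):
            raise ValueError(
                f"{self.canonical_name}: expected {len(schema)} answers for a "
                f"{self.venue_kind}, got {len(self.answers)}"
            )


@dataclass
class AnnotationConsensus:
    canonical_name: str
    venue_kind: str
    consensus_answers: tuple[str, ...] = ()
    retailer_type: str = "unknown"
    health_class: str = "unknown"
    n_annotators: int = 0
    answer_detail: dict[str, str] = field(default_factory=dict)


def _plurality(answers: list[str]) -> str:
    counts = Counter(answers)
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return TIE
    return ranked[0][0]


def majority_vote(responses: Iterable[QuestionnaireResponse]) -> AnnotationConsensus:
    """Per-question plurality over one entity's responses.

    A plurality (not necessarily a majority) suffices; exact top ties yield
    ``"tie"``.  The first question of either schema names the venue type and
    determines the retailer type (a tie there leaves it unknown).
    """
    responses = list(responses)
    if not responses:
        raise ValueError("majority_vote requires at least one response")
    names = {r.canonical_name for r in responses}
    kinds = {r.venue_kind for r in responses}
    if len(names) != 1 or len(kinds) != 1:
        raise ValueError("responses must concern a single (entity, venue_kind)")
    seen_annotators = [r.annotator_id for r in responses]
    if len(set(seen_annotators)) != len(seen_annotators):
        raise ValueError("duplicate annotator for one entity")

    kind = responses[0].venue_kind
    schema = SCHEMAS[kind]
    consensus = tuple(
        _plurality([r.answers[q] for r in responses]) for q in range(len(schema))
    )
    rtype = consensus[0]
    if rtype == TIE or rtype not in RETAILER_TYPES:
        rtype = "unknown"
    return AnnotationConsensus(
        canonical_name=responses[0].canonical_name,
        venue_kind=kind,
        consensus_answers=consensus,
        retailer_type=rtype,
        health_class=health_class_of_type(rtype),
        n_annotators=len(responses),
        answer_detail=dict(zip(schema, consensus)),
    )


def health_class_of_type(retailer_type: str) -> str:
    if retailer_type in HEALTHY_TYPES:
        return "healthy"
    if retailer_type in LESS_HEALTHY_TYPES:
        return "less_healthy"
    return "unknown"


def classify_health(
    consensus: AnnotationConsensus | None,
    tags: Iterable[str] = (),
    tag_type_map: Mapping[str, str] | None = None,
) -> str:
    """Health class from consensus when available, else from listing tags.

    Entities that never reached the questionnaire (fewer than four
    occurrences) are classified by mapping their listing tags through a
    keyword table; the first healthy/less-healthy hit in sorted tag order
    wins, otherwise the class stays unknown.
    """
    if consensus is not None and consensus.retailer_type != "unknown":
        return health_class_of_type(consensus.retailer_type)
    table = DEFAULT_TAG_TYPE_MAP if tag_type_map is None else dict(tag_type_map)
    for tag in sorted(str(t).strip().lower() for t in tags):
        rtype = table.get(tag)
        if rtype is None:
            continue
        cls = health_class_of_type(rtype)
        if cls != "unknown":
            return cls
    return "unknown"
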