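"""Scoring, ordering and filtering of overlap results.

The balance score rewards overlapping elements supported by many articles
on BOTH sides::

    score = min(uniq_a, uniq_b) / max(uniq_a, uniq_b) * (uniq_a + uniq_b)

so (5, 5) -> 10 outranks (1, 100) -> 1.01 despite the smaller total: many
and EQUAL supporting articles are treated as the most reliable evidence.

Filters mirror an interactive panel: corrected-P and odds-ratio thresholds,
predicate-frequency-rank and MeSH-depth cuts, per-position keyword
filter/restrict over the five chain elements, and a top-N cap — applied in
that fixed order with survivor counts recorded per stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .errors import ContractError

POSITIONS = ("subject", "predicate_1", "shared", "predicate_2", "object")


def eq1_score(uniq_a: int, uniq_b: int) -> float:
    """Balance score of two per-side unique-article counts (both >= 1)."""
    if uniq_a < 1 or uniq_b < 1:
        raise ContractError(f"uniq counts must be >= 1: ({uniq_a}, {uniq_b})")
    return min(uniq_a, uniq_b) / max(uniq_a, uniq_b) * (uniq_a + uniq_b)


@dataclass(frozen=True)
class FilterSpec:
    """Declarative filter panel settings.

    ``min_pfr`` keeps rows whose rarest predicate rank is at least the given
    value, i.e. ``min_pfr = 6`` excludes any chain using one of the five
    globally most frequent predicates. Keyword lists are per-position;
    include lists mean "keep only rows matching at least one keyword at that
    position". Matching is case-insensitive substring unless
    ``exact_keywords`` is set.
    """

    max_mean_p_corrected: float | None = None
    min_odds_ratio: float | None = None
    top_n: int | None = None
    min_pfr: int | None = None
    min_mesh_depth: int | None = None
    include_keywords: dict[str, tuple[str, ...]] = field(default_factory=dict)
    exclude_keywords: dict[str, tuple[str, ...]] = field(default_factory=dict)
    exact_keywords: bool = False

    def __post_init__(self):
        for position in list(self.include_keywords) + list(self.exclude_keywords):
            if position not in POSITIONS:
                raise ContractError(f"unknown keyword position {position!r}")
        for position in self.include_keywords:
            inc = set(self.include_keywords[position])
            exc = set(self.exclude_keywords.get(position, ()))
            if inc & exc:
                raise ContractError(
                    f"include/exclude keywords overlap at {position!r}: {inc & exc}"
                )
        if self.top_n is not None and self.top_n <= 0:
            raise ContractError("top_n must be positive")


@dataclass
class RankedResults:
    """An ordered result list plus the bookkeeping of how it got that way."""

    items: list
    order_key: str = "score"
    spec: FilterSpec | None = None
    stage_counts: list[tuple[str, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)


ORDER_KEYS = ("score", "mean_p_corrected", "pfr", "mesh_depth")


def _sort_key(item, key: str):
    # Deterministic total order: primary key, then total support desc,
    # then lexicographic identity.
    tiebreak = (-(item.uniq_a + item.uniq_b), item.identity())
    if key == "score":
        return (-item.score, *tiebreak)
    if key == "mean_p_corrected":
        return (item.mean_p_corrected, *tiebreak)
    if key == "pfr":
        return (-min(item.pfr_1, item.pfr_2), *tiebreak)
    if key == "mesh_depth":
        return (-item.mesh_depth, *tiebreak)
    raise ContractError(f"unknown ordering key {key!r}")


def order_results(results: Sequence, key: str = "score") -> RankedResults:
    """Totally order results by one of the supported keys.

    score -> descending; mean_p_corrected -> ascending; pfr -> rarest
    predicate first (descending min rank); mesh_depth -> most specific
    (deepest) first. Ties break by total support descending, then by the
    lexicographic identity tuple, so the ordering is fully deterministic.
    """
    if key not in ORDER_KEYS:
        raise ContractError(f"unknown ordering key {key!r}; expected {ORDER_KEYS}")
    items = list(results)
    if key == "mesh_depth":
        if any(not hasattr(item, "mesh_depth") for item in items):
            raise ContractError("mesh_depth ordering applies to MeSH results only")
        if any(item.mesh_depth is None for item in items):
            raise ContractError("mesh_depth ordering requires depths for all terms")
    if key == "pfr" and any(not hasattr(item, "pfr_1") for item in items):
        raise ContractError("pfr ordering applies to triple-method results only")
    return RankedResults(
        items=sorted(items, key=lambda item: _sort_key(item, key)), order_key=key
    )


def _min_odds(item) -> float:
    return min(item.odds_ratio_a, item.odds_ratio_b)


def _keyword_match(text: str, keyword: str, exact: bool) -> bool:
    if exact:
        return text.lower() == keyword.lower()
    return keyword.lower() in text.lower()


def _passes_keywords(item, spec: FilterSpec) -> bool:
    for position, keywords in spec.include_keywords.items():
        text = item.position_text(position)
        if not any(_keyword_match(text, kw, spec.exact_keywords) for kw in keywords):
            return False
    for position, keywords in spec.exclude_keywords.items():
        text = item.position_text(position)
        if any(_keyword_match(text, kw, spec.exact_keywords) for kw in keywords):
            return False
    return True


def apply_filters(results, spec: FilterSpec) -> RankedResults:
    """Apply the filter stages in fixed order, recording survivor counts.

    Stage order: corrected-P -> odds ratio -> PFR / MeSH depth -> keywords
    -> top-N. An empty survivor list is a valid outcome, never an error.
    If given a :class:`RankedResults` the existing ordering is preserved;
    plain sequences are ordered by score first so top-N is well defined.
    """
    if isinstance(results, RankedResults):
        ranked = results
    else:
        ranked = order_results(results, "score")
    items = list(ranked.items)
    stages: list[tuple[str, int]] = [("input", len(items))]

    if spec.max_mean_p_corrected is not None:
        items = [i for i in items if i.mean_p_corrected <= spec.max_mean_p_corrected]
    stages.append(("max_mean_p_corrected", len(items)))

    if spec.min_odds_ratio is not None:
        items = [i for i in items if _min_odds(i) >= spec.min_odds_ratio]
    stages.append(("min_odds_ratio", len(items)))

    if spec.min_pfr is not None:
        items = [i for i in items if min(i.pfr_1, i.pfr_2) >= spec.min_pfr]
    if spec.min_mesh_depth is not None:
        items = [
            i
            for i in items
            if i.mesh_depth is not None and i.mesh_depth >= spec.min_mesh_depth
        ]
    stages.append(("pfr_depth", len(items)))

    if spec.include_keywords or spec.exclude_keywords:
        items = [i for i in items if _passes_keywords(i, spec)]
    stages.append(("keywords", len(items)))

    if spec.top_n is not None:
        items = items[: spec.top_n]
    stages.append(("top_n", len(items)))

    return RankedResults(
        items=items, order_key=ranked.order_key, spec=spec, stage_counts=stages
    )


# Dynamic first-pass display rules. The thresholds are this package's
# parameterization: small result sets are shown unfiltered, larger ones are
# capped, and very large ones additionally drop the most frequent (least
# informative) predicates.
DYNAMIC_SMALL = 50
DYNAMIC_LARGE = 1000
DYNAMIC_TOP_N = 100
DYNAMIC_PFR_EXCLUDE = 5


def dynamic_defaults(results: Sequence) -> FilterSpec:
    """First-pass filter settings adapted to the result-set size."""
    n = len(results)
    if n <= DYNAMIC_SMALL:
        return FilterSpec()
    if n <= DYNAMIC_LARGE:
        return FilterSpec(top_n=DYNAMIC_TOP_N)
    return FilterSpec(top_n=DYNAMIC_TOP_N, min_pfr=DYNAMIC_PFR_EXCLUDE + 1)


def combine_specs(first: FilterSpec, second: FilterSpec) -> FilterSpec:
    """The stricter combination of two filter panels."""

    def stricter(x, y, pick):
        if x is None:
            return y
        if y is None:
            return x
        return pick(x, y)

    merged_include = dict(first.include_keywords)
    for position, kws in second.include_keywords.items():
        merged_include[position] = tuple(
            dict.fromkeys(merged_include.get(position, ()) + tuple(kws))
        )
    merged_exclude = dict(first.exclude_keywords)
    for position, kws in second.exclude_keywords.items():
        merged_exclude[position] = tuple(
            dict.fromkeys(merged_exclude.get(position, ()) + tuple(kws))
        )
    return FilterSpec(
        max_mean_p_corrected=stricter(
            first.max_mean_p_corrected, second.max_mean_p_corrected, min
        ),
        min_odds_ratio=stricter(first.min_odds_ratio, second.min_odds_ratio, max),
        top_n=stricter(first.top_n, second.top_n, min),
        min_pfr=stricter(first.min_pfr, second.min_pfr, max),
        min_mesh_depth=stricter(first.min_mesh_depth, second.min_mesh_depth, max),
        include_keywords=merged_include,
        exclude_keywords=merged_exclude,
        exact_keywords=first.exact_keywords or second.exact_keywords,
    )
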