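"""Overlap between two enriched article sets: shared terms and chains.

Single-term overlap intersects the surviving enrichment lists of the two
sets. Triple overlap chains enriched triples: every enriched triple
(s, P1, x) of set A whose object x equals the subject of an enriched triple
(x, P2, o) of set B yields one candidate mechanism chain A-side -> x ->
B-side, provided x is rarer than the linking-term frequency cap. Direction
is strict: A-objects join B-subjects, never the reverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ContractError
from .enrich import EnrichmentResult
from .ranking import eq1_score
from .store import KnowledgeStore, TripleKey, predicate_ranks
from .sets import ArticleSet

DEFAULT_LINKING_THRESHOLD = 150_000


@dataclass
class SharedTerm:
    """A term enriched in both article sets (mesh or concept method)."""

    key: str
    name: str
    uniq_a: int
    uniq_b: int
    p_corrected_a: float
    p_corrected_b: float
    odds_ratio_a: float
    odds_ratio_b: float
    score: float
    mesh_depth: int | None = None

    @property
    def mean_p_corrected(self) -> float:
        return (self.p_corrected_a + self.p_corrected_b) / 2

    def identity(self) -> tuple:
        return (self.key,)

    def position_text(self, position: str) -> str:
        return self.name if position == "shared" else ""


@dataclass
class MechanismChain:
    """subjectA -predicate1-> sharedTerm -predicate2-> objectB."""

    subject_id: str
    subject_name: str
    subject_semtype: str
    predicate_1: str
    shared_id: str
    shared_name: str
    shared_semtype: str
    predicate_2: str
    object_id: str
    object_name: str
    object_semtype: str
    uniq_a: int
    uniq_b: int
    p_corrected_a: float
    p_corrected_b: float
    odds_ratio_a: float
    odds_ratio_b: float
    score: float
    pfr_1: int
    pfr_2: int
    set_a: str = ""
    set_b: str = ""
    articles_a: list[int] = field(default_factory=list)
    articles_b: list[int] = field(default_factory=list)

    @property
    def mean_p_corrected(self) -> float:
        return (self.p_corrected_a + self.p_corrected_b) / 2

    @property
    def triple_a(self) -> TripleKey:
        return (self.subject_id, self.predicate_1, self.shared_id)

    @property
    def triple_b(self) -> TripleKey:
        return (self.shared_id, self.predicate_2, self.object_id)

    def identity(self) -> tuple:
        """5-tuple of IDs and predicates identifying the chain."""
        return (
            self.subject_id,
            self.predicate_1,
            self.shared_id,
            self.predicate_2,
            self.object_id,
        )

    def position_text(self, position: str) -> str:
        return {
            "subject": self.subject_name,
            "predicate_1": self.predicate_1,
            "shared": self.shared_name,
            "predicate_2": self.predicate_2,
            "object": self.object_name,
        }[position]


def overlap_single(
    result_a: EnrichmentResult,
    result_b: EnrichmentResult,
    store: KnowledgeStore | None = None,
) -> list[SharedTerm]:
    """Terms enriched in BOTH sets (mesh or concept method)."""
    if result_a.method != result_b.method:
        raise ContractError(
            f"method mismatch: {result_a.method!r} vs {result_b.method!r}"
        )
    if result_a.method == "triple":
        raise ContractError("use overlap_triples for the triple method")

    by_key_a = {r.key: r for r in result_a.surviving}
    by_key_b = {r.key: r for r in result_b.surviving}
    shared: list[SharedTerm] = []
    for key in sorted(set(by_key_a) & set(by_key_b)):
        rec_a, rec_b = by_key_a[key], by_key_b[key]
        name = key
        depth = None
        if store is not None:
            if result_a.method == "mesh":
                name = store.descriptor_names.get(key, key)
                depth = store.mesh_tree.depth(key)
            else:
                name = store.concept_name(key)
        shared.append(
            SharedTerm(
                key=key,
                name=name,
                uniq_a=rec_a.uniq,
                uniq_b=rec_b.uniq,
                p_corrected_a=rec_a.p_corrected,
                p_corrected_b=rec_b.p_corrected,
                odds_ratio_a=rec_a.odds_ratio,
                odds_ratio_b=rec_b.odds_ratio,
                score=eq1_score(rec_a.uniq, rec_b.uniq),
                mesh_depth=depth,
            )
        )
    return shared


def overlap_triples(
    store: KnowledgeStore,
    result_a: EnrichmentResult,
    result_b: EnrichmentResult,
    linking_threshold: int = DEFAULT_LINKING_THRESHOLD,
) -> list[MechanismChain]:
    """Chain enriched triples of A into enriched triples of B.

    The linking term (A-object = B-subject) must occur fewer than
    ``linking_threshold`` times globally, counted on the (article, slot)
    occurrence scale; the cap applies only to the linking position. All
    predicates are included deliberately — common relations can still carry
    signal when few chains survive.
    """
    if result_a.method != "triple" or result_b.method != "triple":
        raise ContractError("overlap_triples requires triple-method results")
    if linking_threshold <= 0:
        raise ContractError("linking_threshold must be positive")

    ranks = predicate_ranks(store)
    a_by_object: dict[str, list] = {}
    for rec in result_a.surviving:
        a_by_object.setdefault(rec.key[2], []).append(rec)

    chains: list[MechanismChain] = []
    for rec_b in result_b.surviving:
        link = rec_b.key[0]
        if link not in a_by_object:
            continue
        if store.concept_occurrence_freq.get(link, 0) >= linking_threshold:
            continue
        for rec_a in a_by_object[link]:
            chains.append(
                MechanismChain(
                    subject_id=rec_a.key[0],
                    subject_name=store.concept_name(rec_a.key[0]),
                    subject_semtype=store.concept_semtypes.get(rec_a.key[0], ""),
                    predicate_1=rec_a.key[1],
                    shared_id=link,
                    shared_name=store.concept_name(link),
                    shared_semtype=store.concept_semtypes.get(link, ""),
                    predicate_2=rec_b.key[1],
                    object_id=rec_b.key[2],
                    object_name=store.concept_name(rec_b.key[2]),
                    object_semtype=store.concept_semtypes.get(rec_b.key[2], ""),
                    uniq_a=rec_a.uniq,
                    uniq_b=rec_b.uniq,
                    p_corrected_a=rec_a.p_corrected,
                    p_corrected_b=rec_b.p_corrected,
                    odds_ratio_a=rec_a.odds_ratio,
                    odds_ratio_b=rec_b.odds_ratio,
                    score=eq1_score(rec_a.uniq, rec_b.uniq),
                    pfr_1=ranks[rec_a.key[1]].rank,
                    pfr_2=ranks[rec_b.key[1]].rank,
                    set_a=result_a.set_name,
                    set_b=result_b.set_name,
                )
            )
    chains.sort(key=lambda c: c.identity())
    return chains


def attach_provenance(
    store: KnowledgeStore,
    chains: list[MechanismChain],
    set_a: ArticleSet,
    set_b: ArticleSet,
) -> list[MechanismChain]:
    """Fill per-side supporting article-ID lists on each chain, in place.

    Side A = member articles of set A containing triple 1; side B likewise
    for triple 2. List lengths must match the uniq counts recorded at
    enrichment time — a mismatch means the indexes and the enrichment
    disagree, which is an internal error.
    """
    for chain in chains:
        articles_a = sorted(store.articles_with_triple(chain.triple_a) & set_a.member_ids)
        articles_b = sorted(store.articles_with_triple(chain.triple_b) & set_b.member_ids)
        if len(articles_a) != chain.uniq_a or len(articles_b) != chain.uniq_b:
            raise ContractError(
                f"provenance mismatch for chain {chain.identity()}: "
                f"{len(articles_a)}/{chain.uniq_a} A-side, "
                f"{len(articles_b)}/{chain.uniq_b} B-side"
            )
        if not articles_a or not articles_b:
            raise ContractError(f"empty support for chain {chain.identity()}")
        chain.articles_a = articles_a
        chain.articles_b = articles_b
    return chains
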