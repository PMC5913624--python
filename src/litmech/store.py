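"""Indexed corpus: inverted indexes and global background frequencies.

The store replaces a graph database with plain inverted indexes. Evidence is
deduplicated to (article, triple) and (article, descriptor) pairs before any
counting, so repeated mentions inside one abstract never inflate a count.

Two frequency notions coexist for concepts:

* ``concept_article_freq`` — distinct articles containing the concept as
  subject OR object (the natural 2x2-table background unit);
* ``concept_occurrence_freq`` — (article, slot) occurrences: an article
  contributes once for the concept-as-subject and once for
  concept-as-object. Published linking-term frequency caps (the 150,000
  default) are expressed on this occurrence scale.
"""

from __future__ import annotations

import hashlib
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ContractError
from .io import MeshAnnotation, MeshTree, Predication

TripleKey = tuple[str, str, str]


@dataclass(frozen=True, slots=True)
class PredicateRank:
    """Global frequency rank of one predicate; rank 1 = most frequent."""

    predicate: str
    count: int
    rank: int


@dataclass
class KnowledgeStore:
    """Immutable-after-build indexed corpus.

    Attributes ending in ``_freq`` are global background frequencies over
    the whole article universe (the union of articles seen in the
    predication and annotation inputs).
    """

    n_articles: int = 0
    articles: set[int] = field(default_factory=set)
    # forward indexes
    article_triples: dict[int, set[TripleKey]] = field(default_factory=dict)
    article_descriptors: dict[int, set[str]] = field(default_factory=dict)
    # inverted indexes
    triple_articles: dict[TripleKey, set[int]] = field(default_factory=dict)
    concept_articles: dict[str, set[int]] = field(default_factory=dict)
    concept_subject_articles: dict[str, set[int]] = field(default_factory=dict)
    concept_object_articles: dict[str, set[int]] = field(default_factory=dict)
    descriptor_articles: dict[str, set[int]] = field(default_factory=dict)
    # global frequencies
    global_triple_freq: dict[TripleKey, int] = field(default_factory=dict)
    global_mesh_freq: dict[str, int] = field(default_factory=dict)
    concept_article_freq: dict[str, int] = field(default_factory=dict)
    concept_occurrence_freq: dict[str, int] = field(default_factory=dict)
    predicate_freq: dict[str, int] = field(default_factory=dict)
    # display names and semantic types, keyed by concept/descriptor id
    concept_names: dict[str, str] = field(default_factory=dict)
    concept_semtypes: dict[str, str] = field(default_factory=dict)
    descriptor_names: dict[str, str] = field(default_factory=dict)
    mesh_tree: MeshTree = field(default_factory=MeshTree)
    fingerprint: str = ""

    # ------------------------------------------------------------------ API
    def articles_with_triple(self, key: TripleKey) -> set[int]:
        return set(self.triple_articles.get(key, ()))

    def articles_with_concept(self, concept_id: str) -> set[int]:
        return set(self.concept_articles.get(concept_id, ()))

    def articles_with_descriptor(self, descriptor_id: str) -> set[int]:
        return set(self.descriptor_articles.get(descriptor_id, ()))

    def concept_name(self, concept_id: str) -> str:
        return self.concept_names.get(concept_id, concept_id)

    def save(self, path: str | Path) -> None:
        """Serialize the store to a single cache file."""
        with open(path, "wb") as handle:
            pickle.dump(self, handle, protocol=pickle.HIGHEST_PROTOCOL)

    @staticmethod
    def load(path: str | Path) -> "KnowledgeStore":
        with open(path, "rb") as handle:
            store = pickle.load(handle)
        if not isinstance(store, KnowledgeStore):
            raise ContractError(f"{path} is not a knowledge-store cache file")
        return store


def build_store(
    predications: Sequence[Predication],
    mesh_annotations: Sequence[MeshAnnotation] = (),
    mesh_tree: MeshTree | None = None,
) -> KnowledgeStore:
    """Build all indexes from parsed input records.

    Duplicate (article, triple) and (article, descriptor) rows collapse to a
    single evidence link. The article universe is the union of article IDs
    in both inputs; construction is deterministic and independent of row
    order.
    """
    if not predications and not mesh_annotations:
        raise ContractError("empty corpus: no predications and no annotations")

    store = KnowledgeStore(mesh_tree=mesh_tree or MeshTree())

    # Dedup to (article, triple); keep per-pair predicate occurrence once.
    pair_set: set[tuple[int, TripleKey]] = set()
    for p in predications:
        pair = (p.article_id, p.key())
        if pair in pair_set:
            continue
        pair_set.add(pair)
        store.articles.add(p.article_id)
        store.article_triples.setdefault(p.article_id, set()).add(p.key())
        store.triple_articles.setdefault(p.key(), set()).add(p.article_id)
        store.concept_subject_articles.setdefault(p.subject_id, set()).add(p.article_id)
        store.concept_object_articles.setdefault(p.object_id, set()).add(p.article_id)
        store.concept_names.setdefault(p.subject_id, p.subject_name)
        store.concept_names.setdefault(p.object_id, p.object_name)
        store.concept_semtypes.setdefault(p.subject_id, p.subject_semtype)
        store.concept_semtypes.setdefault(p.object_id, p.object_semtype)
        store.predicate_freq[p.predicate] = store.predicate_freq.get(p.predicate, 0) + 1

    mesh_pairs: set[tuple[int, str]] = set()
    for m in mesh_annotations:
        store.articles.add(m.article_id)
        store.descriptor_names.setdefault(m.descriptor_id, m.descriptor_name)
        if not m.is_major:
            continue  # stored in the universe but never indexed for enrichment
        pair = (m.article_id, m.descriptor_id)
        if pair in mesh_pairs:
            continue
        mesh_pairs.add(pair)
        store.article_descriptors.setdefault(m.article_id, set()).add(m.descriptor_id)
        store.descriptor_articles.setdefault(m.descriptor_id, set()).add(m.article_id)

    for concept in set(store.concept_subject_articles) | set(store.concept_object_articles):
        subj = store.concept_subject_articles.get(concept, set())
        obj = store.concept_object_articles.get(concept, set())
        store.concept_articles[concept] = subj | obj
        store.concept_article_freq[concept] = len(subj | obj)
        store.concept_occurrence_freq[concept] = len(subj) + len(obj)

    store.global_triple_freq = {k: len(v) for k, v in store.triple_articles.items()}
    store.global_mesh_freq = {k: len(v) for k, v in store.descriptor_articles.items()}
    store.n_articles = len(store.articles)
    store.fingerprint = _fingerprint(pair_set, mesh_pairs)
    return store


def _fingerprint(
    triple_pairs: Iterable[tuple[int, TripleKey]],
    mesh_pairs: Iterable[tuple[int, str]],
) -> str:
    digest = hashlib.sha256()
    for article, (s, p, o) in sorted(triple_pairs):
        digest.update(f"T\t{article}\t{s}\t{p}\t{o}\n".encode())
    for article, descriptor in sorted(mesh_pairs):
        digest.update(f"M\t{article}\t{descriptor}\n".encode())
    return digest.hexdigest()


def predicate_ranks(store: KnowledgeStore) -> dict[str, PredicateRank]:
    """Rank predicates by global frequency; rank 1 = most frequent.

    Ties break by predicate string ascending, so the ranking is a
    deterministic permutation of 1..K.
    """
    ordered = sorted(store.predicate_freq.items(), key=lambda kv: (-kv[1], kv[0]))
    return {
        predicate: PredicateRank(predicate=predicate, count=count, rank=i)
        for i, (predicate, count) in enumerate(ordered, start=1)
    }
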