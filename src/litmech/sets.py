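"""Named article sets and per-set unique-article occurrence counts."""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ContractError
from .store import KnowledgeStore, TripleKey

METHODS = ("mesh", "concept", "triple")


@dataclass
class ArticleSet:
    """A named set of article IDs restricted to store coverage.

    ``member_ids`` are the requested IDs actually present in the store;
    contingency denominators are built from members only, so uploaded IDs
    the corpus never saw cannot dilute the statistics.
    """

    name: str
    requested_ids: list[int]
    member_ids: set[int] = field(default_factory=set)

    @property
    def n_members(self) -> int:
        return len(self.member_ids)

    @property
    def n_absent(self) -> int:
        return len(self.requested_ids) - self.n_members

    def member_hash(self) -> str:
        import hashlib

        digest = hashlib.sha256()
        for article in sorted(self.member_ids):
            digest.update(f"{article}\n".encode())
        return digest.hexdigest()


def create_article_set(store: KnowledgeStore, name: str, ids: list[int]) -> ArticleSet:
    """Materialize an article set, intersecting the IDs with store coverage."""
    if not ids:
        raise ContractError(f"article set {name!r}: empty ID list")
    members = set(ids) & store.articles
    if not members:
        raise ContractError(f"article set {name!r} has no coverage in the store")
    return ArticleSet(name=name, requested_ids=list(ids), member_ids=members)


def occurrences(
    store: KnowledgeStore, article_set: ArticleSet, method: str
) -> dict[str | TripleKey, int]:
    """Per-set unique-article counts for every key present in the set.

    mesh    -> major-topic descriptor counts;
    concept -> distinct member articles containing the concept as subject or
               object (one article counts once even if the concept fills
               both slots in it);
    triple  -> distinct member articles containing the directed triple.
    """
    if method not in METHODS:
        raise ContractError(f"unknown method {method!r}; expected one of {METHODS}")
    members = article_set.member_ids
    counts: dict[str | TripleKey, int] = {}
    if method == "triple":
        for article in members:
            for key in store.article_triples.get(article, ()):
                counts[key] = counts.get(key, 0) + 1
    elif method == "concept":
        seen: dict[str, set[int]] = {}
        for article in members:
            for key in store.article_triples.get(article, ()):
                seen.setdefault(key[0], set()).add(article)
                seen.setdefault(key[2], set()).add(article)
        counts = {concept: len(arts) for concept, arts in seen.items()}
    else:  # mesh
        for article in members:
            for descriptor in store.article_descriptors.get(article, ()):
                counts[descriptor] = counts.get(descriptor, 0) + 1
    return counts
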