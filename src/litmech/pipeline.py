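"""End-to-end convenience wrappers over the module-level building blocks."""

from __future__ import annotations

from pathlib import Path

from .enrich import DEFAULT_ALPHA, enrich
from .overlap import (
    DEFAULT_LINKING_THRESHOLD,
    MechanismChain,
    SharedTerm,
    attach_provenance,
    overlap_single,
    overlap_triples,
)
from .sets import ArticleSet, create_article_set
from .store import KnowledgeStore


def discover_chains(
    store: KnowledgeStore,
    ids_a: list[int],
    ids_b: list[int],
    name_a: str = "set A",
    name_b: str = "set B",
    alpha: float = DEFAULT_ALPHA,
    linking_threshold: int = DEFAULT_LINKING_THRESHOLD,
    cache_dir: str | Path | None = None,
) -> list[MechanismChain]:
    """Full triple-method pipeline: sets -> enrichment -> chains -> provenance."""
    set_a = create_article_set(store, name_a, ids_a)
    set_b = create_article_set(store, name_b, ids_b)
    result_a = enrich(store, set_a, "triple", alpha=alpha, cache_dir=cache_dir)
    result_b = enrich(store, set_b, "triple", alpha=alpha, cache_dir=cache_dir)
    chains = overlap_triples(store, result_a, result_b, linking_threshold)
    return attach_provenance(store, chains, set_a, set_b)


def discover_shared_terms(
    store: KnowledgeStore,
    ids_a: list[int],
    ids_b: list[int],
    method: str = "mesh",
    name_a: str = "set A",
    name_b: str = "set B",
    alpha: float = DEFAULT_ALPHA,
    cache_dir: str | Path | None = None,
) -> list[SharedTerm]:
    """Full single-term pipeline for the mesh or concept method."""
    set_a = create_article_set(store, name_a, ids_a)
    set_b = create_article_set(store, name_b, ids_b)
    result_a = enrich(store, set_a, method, alpha=alpha, cache_dir=cache_dir)
    result_b = enrich(store, set_b, method, alpha=alpha, cache_dir=cache_dir)
    return overlap_single(result_a, result_b, store=store)
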