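"""Shared-term intersection, triple chaining, direction, provenance."""

import numpy as np
import pytest

from conftest import P, make_toy_corpus
from litmech import (
    ContractError,
    build_store,
    create_article_set,
    enrich,
    overlap_single,
    overlap_triples,
    attach_provenance,
)
from litmech.enrich import EnrichmentRecord, EnrichmentResult


def _result(set_name, method, keys, uniq=4, n_members=10):
    """Enrichment result whose surviving list is exactly `keys`."""
    records = [
        EnrichmentRecord(key=k, uniq=uniq, global_count=uniq, p=1e-9,
                         p_corrected=1e-8, odds_ratio=50.0)
        for k in keys
    ]
    return EnrichmentResult(set_name=set_name, method=method, alpha=1e-5,
                            n_members=n_members, records=records)


# ------------------------------------------------------------ single terms

def test_shared_terms_are_key_intersection():
    a = _result("A", "concept", ["X", "Y"])
    b = _result("B", "concept", ["Y", "Z"])
    shared = overlap_single(a, b)
    assert [t.key for t in shared] == ["Y"]
    assert shared[0].score == 8.0  # uniq 4 and 4: ratio 1, sum 8
    assert shared[0].mean_p_corrected == pytest.approx(1e-8)


def test_disjoint_enrichments_share_nothing():
    assert overlap_single(_result("A", "mesh", ["X"]),
                          _result("B", "mesh", ["Y"])) == []


def test_method_mismatch_rejected():
    with pytest.raises(ContractError, match="mismatch"):
        overlap_single(_result("A", "mesh", ["X"]), _result("B", "concept", ["X"]))
    with pytest.raises(ContractError):
        overlap_single(_result("A", "triple", []), _result("B", "triple", []))


# ------------------------------------------------------------------ chains

def _chain_store(extra=()):
    """ERG->SP1 in A-articles 1-4, SP1->PCA in B-articles 11-14, background."""
    rows = [P(a, "ERG", "INTERACTS_WITH", "SP1") for a in (1, 2, 3, 4)]
    rows += [P(b, "SP1", "ASSOCIATED_WITH", "PCA") for b in (11, 12, 13, 14)]
    rows += [P(a, "F1", "AFFECTS", "F2") for a in range(21, 200)]
    rows += list(extra)
    return build_store(rows)


def _pipeline(store, ids_a, ids_b, threshold=1000, alpha=1e-5):
    set_a = create_article_set(store, "A", ids_a)
    set_b = create_article_set(store, "B", ids_b)
    result_a = enrich(store, set_a, "triple", alpha=alpha)
    result_b = enrich(store, set_b, "triple", alpha=alpha)
    chains = overlap_triples(store, result_a, result_b, threshold)
    return chains, set_a, set_b, result_a, result_b


def test_single_chain_found_and_scored():
    store = _chain_store()
    chains, *_ = _pipeline(store, [1, 2, 3, 4], [11, 12, 13, 14])
    assert len(chains) == 1
    chain = chains[0]
    assert chain.identity() == ("ERG", "INTERACTS_WITH", "SP1",
                                "ASSOCIATED_WITH", "PCA")
    assert chain.uniq_a == 4 and chain.uniq_b == 4 and chain.score == 8.0
    assert chain.set_a == "A" and chain.set_b == "B"


def test_linking_term_at_threshold_excluded():
    store = _chain_store()
    # SP1 occurrence count = 4 (as object in A) + 4 (as subject in B) = 8
    assert store.concept_occurrence_freq["SP1"] == 8
    chains, *_ = _pipeline(store, [1, 2, 3, 4], [11, 12, 13, 14], threshold=8)
    assert chains == []
    chains, *_ = _pipeline(store, [1, 2, 3, 4], [11, 12, 13, 14], threshold=9)
    assert len(chains) == 1


def test_threshold_relaxation_is_monotone():
    rng = np.random.default_rng(3)
    for _ in range(5):
        rows, ids_a, ids_b = make_toy_corpus(rng)
        store = build_store(rows)
        previous = set()
        for threshold in (2, 5, 10, 100):
            chains, *_ = _pipeline(store, ids_a, ids_b, threshold, alpha=0.5)
            identities = {c.identity() for c in chains}
            assert previous <= identities
            previous = identities


def test_cartesian_chaining():
    extra = [P(a, "ERG2", "CAUSES", "SP1") for a in (1, 2, 3, 4)]
    extra += [P(b, "SP1", "TREATS", "PCA2") for b in (11, 12, 13, 14)]
    extra += [P(b, "SP1", "CAUSES", "PCA3") for b in (11, 12, 13, 14)]
    store = _chain_store(extra)
    chains, *_ = _pipeline(store, [1, 2, 3, 4], [11, 12, 13, 14])
    # 2 enriched A-triples into SP1 x 3 enriched B-triples out of SP1
    assert len(chains) == 6


def test_direction_is_strict_a_object_to_b_subject():
    # the only chain runs B-object -> A-subject; A->B must find nothing
    rows = [P(a, "SP1", "INTERACTS_WITH", "ERG") for a in (1, 2, 3, 4)]
    rows += [P(b, "PCA", "ASSOCIATED_WITH", "SP1") for b in (11, 12, 13, 14)]
    rows += [P(a, "F1", "AFFECTS", "F2") for a in range(21, 200)]
    store = build_store(rows)
    chains, *_ = _pipeline(store, [1, 2, 3, 4], [11, 12, 13, 14])
    assert chains == []
    # swapping the sets recovers the chain, so the convention is directional
    reverse_chains, *_ = _pipeline(store, [11, 12, 13, 14], [1, 2, 3, 4])
    assert len(reverse_chains) == 1


def test_provenance_lists_match_uniq_counts():
    store = _chain_store()
    chains, set_a, set_b, *_ = _pipeline(store, [1, 2, 3, 4], [11, 12, 13, 14])
    attach_provenance(store, chains, set_a, set_b)
    chain = chains[0]
    assert chain.articles_a == [1, 2, 3, 4]
    assert chain.articles_b == [11, 12, 13, 14]
    assert len(chain.articles_a) == chain.uniq_a
    assert len(chain.articles_b) == chain.uniq_b


def test_provenance_matches_naive_recount_on_toy_corpus():
    rng = np.random.default_rng(11)
    rows, ids_a, ids_b = make_toy_corpus(rng)
    store = build_store(rows)
    chains, set_a, set_b, *_ = _pipeline(store, ids_a, ids_b, 100, alpha=0.5)
    attach_provenance(store, chains, set_a, set_b)
    for chain in chains:
        expected_a = sorted({r.article_id for r in rows
                             if r.key() == chain.triple_a
                             and r.article_id in set_a.member_ids})
        expected_b = sorted({r.article_id for r in rows
                             if r.key() == chain.triple_b
                             and r.article_id in set_b.member_ids})
        assert chain.articles_a == expected_a
        assert chain.articles_b == expected_b
        assert chain.shared_id in {r.object_id for r in rows
                                   if r.article_id in set_a.member_ids}
        assert chain.shared_id in {r.subject_id for r in rows
                                   if r.article_id in set_b.member_ids}


def test_overlap_requires_triple_method():
    store = _chain_store()
    with pytest.raises(ContractError):
        overlap_triples(store, _result("A", "mesh", []), _result("B", "mesh", []))
    with pytest.raises(ContractError, match="positive"):
        overlap_triples(store, _result("A", "triple", []),
                        _result("B", "triple", []), linking_threshold=0)
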