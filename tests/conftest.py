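"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest

from litmech import (
    MeshAnnotation,
    MeshTree,
    Predication,
    build_store,
)


def P(article, s, p, o, **kw):
    """Terse predication constructor for handcrafted corpora."""
    return Predication(
        article_id=article,
        subject_id=s,
        subject_name=kw.get("sn", s.lower()),
        subject_semtype=kw.get("st", "gngm"),
        predicate=p,
        object_id=o,
        object_name=kw.get("on", o.lower()),
        object_semtype=kw.get("ot", "dsyn"),
    )


def M(article, descriptor, major=True, name=None):
    return MeshAnnotation(
        article_id=article,
        descriptor_id=descriptor,
        descriptor_name=name or descriptor.lower(),
        is_major=major,
    )


@pytest.fixture
def tiny_predications():
    """Six articles: a planted A->X->B chain plus background noise.

    Articles 1-2 carry (ERG, INTERACTS_WITH, SP1); articles 11-12 carry
    (SP1, ASSOCIATED_WITH, PCA); the rest is background.
    """
    return [
        P(1, "ERG", "INTERACTS_WITH", "SP1"),
        P(2, "ERG", "INTERACTS_WITH", "SP1"),
        P(2, "ERG", "INTERACTS_WITH", "SP1"),  # duplicate mention, same article
        P(11, "SP1", "ASSOCIATED_WITH", "PCA"),
        P(12, "SP1", "ASSOCIATED_WITH", "PCA"),
        P(21, "AAA", "AFFECTS", "BBB"),
        P(22, "BBB", "AFFECTS", "CCC"),
        P(23, "AAA", "AFFECTS", "CCC"),
    ]


@pytest.fixture
def tiny_mesh():
    return [
        M(1, "D000001"),
        M(2, "D000001"),
        M(11, "D000002"),
        M(12, "D000002"),
        M(21, "D000003", major=False),
        M(30, "D000003"),  # article with MeSH but no triples
    ]


@pytest.fixture
def tiny_tree():
    tree = MeshTree()
    tree.add("D000001", "C04.557.470")
    tree.add("D000002", "C04.557")
    tree.add("D000002", "C04")
    tree.add("D000003", "C04.111.222.333")
    return tree


@pytest.fixture
def tiny_store(tiny_predications, tiny_mesh, tiny_tree):
    return build_store(tiny_predications, tiny_mesh, tiny_tree)


# --------------------------------------------------------------- oracles

def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher P by exhaustive hypergeometric enumeration.

    Rational arithmetic throughout; a table with the observed margins is
    included when its probability does not exceed the observed table's by
    more than the 1e-7 relative tie tolerance.
    """
    row1, col1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0

    def pmf(k: int) -> Fraction:
        if k < 0 or k > row1 or col1 - k < 0 or col1 - k > n - row1:
            return Fraction(0)
        return Fraction(math.comb(row1, k) * math.comb(n - row1, col1 - k),
                        math.comb(n, col1))

    observed = pmf(a)
    if observed == 0:
        return 1.0
    cutoff = observed * (Fraction(10**7 + 1, 10**7))
    total = sum(
        (mass for k in range(0, min(row1, col1) + 1)
         if (mass := pmf(k)) <= cutoff),
        Fraction(0),
    )
    return float(min(total, Fraction(1)))


def bh_oracle(pvalues) -> list[float]:
    """Plain-Python step-up definition of the BH adjustment."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    suffix_min = math.inf
    for position in range(m - 1, -1, -1):
        index = order[position]
        term = (pvalues[index] * m) / (position + 1)
        suffix_min = min(suffix_min, term)
        adjusted[index] = min(suffix_min, 1.0)
    return adjusted


def make_toy_corpus(rng: np.random.Generator):
    """A random <=50-article corpus for oracle-equivalence checks.

    Returns (predications, pmids_a, pmids_b). Small concept and predicate
    vocabularies guarantee repeated triples, so enrichment lists at a
    relaxed alpha are nonempty and chain overlaps occur.
    """
    n_articles = int(rng.integers(20, 51))
    articles = list(range(1, n_articles + 1))
    third = n_articles // 3
    pmids_a, pmids_b = articles[:third], articles[third: 2 * third]
    concepts = [f"C{i}" for i in range(1, 11)]
    predicates = ["ASSOCIATED_WITH", "AFFECTS", "INHIBITS"]
    predications = []
    for article in articles:
        for _ in range(int(rng.integers(1, 4))):
            s, o = rng.choice(concepts, size=2, replace=False)
            predications.append(
                P(article, str(s), predicates[int(rng.integers(3))], str(o))
            )
    return predications, pmids_a, pmids_b
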