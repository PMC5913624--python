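"""Synthetic corpora with planted mechanisms and known ground truth.

The generator emulates the statistical structure the discovery engine
assumes: two topic-focused article sets and a large background corpus;
background triples whose concepts follow a Zipf-like frequency law (a few
ubiquitous concepts, a long tail of rare ones); planted mechanistic chains
subject -> link -> object whose two triples recur across a fixed fraction
(penetrance) of each set's articles; and injected "Patients/Cells"-like
common terms that are globally so frequent they should be removed by the
linking-term frequency cap, not by the enrichment statistics.

Planted occurrences are placed deterministically (exactly
``ceil(penetrance * n)`` articles) so the contingency tables of planted
keys are known in advance; a Bernoulli mode exists for power studies. The
MeSH side mirrors the concept side — each planted link concept has a
descriptor planted in the same articles — so all three enrichment methods
are testable from one corpus.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ContractError
from .io import (
    MeshAnnotation,
    MeshTree,
    Predication,
    write_mesh_annotations,
    write_mesh_tree,
    write_pmid_list,
    write_predications,
)

# Predicate vocabulary with descending global weights, so predicate
# frequency ranks are meaningful on synthetic data.
PREDICATES = [
    ("ASSOCIATED_WITH", 30),
    ("AFFECTS", 20),
    ("PART_OF", 15),
    ("COEXISTS_WITH", 10),
    ("PROCESS_OF", 8),
    ("TREATS", 6),
    ("INTERACTS_WITH", 4),
    ("CAUSES", 3),
    ("INHIBITS", 2),
    ("STIMULATES", 2),
]

SEMTYPES = ["gngm", "dsyn", "aapp", "phsu", "celf"]


@dataclass(frozen=True, slots=True)
class PlantedChain:
    """One ground-truth mechanism: subject -P1-> link -P2-> object."""

    subject: str
    predicate_1: str
    link: str
    predicate_2: str
    object: str
    penetrance_a: float
    penetrance_b: float

    def identity(self) -> tuple[str, str, str, str, str]:
        return (self.subject, self.predicate_1, self.link, self.predicate_2,
                self.object)


def default_planted_chains(n: int = 5, penetrance: float = 0.1) -> list[PlantedChain]:
    predicates = ["INHIBITS", "STIMULATES", "INTERACTS_WITH", "CAUSES", "TREATS"]
    chains = []
    for i in range(1, n + 1):
        chains.append(
            PlantedChain(
                subject=f"CSUBJ{i:02d}",
                predicate_1=predicates[(i - 1) % len(predicates)],
                link=f"CLINK{i:02d}",
                predicate_2=predicates[i % len(predicates)],
                object=f"COBJ{i:02d}",
                penetrance_a=penetrance,
                penetrance_b=penetrance,
            )
        )
    return chains


@dataclass
class CorpusConfig:
    """Study conditions for one synthetic corpus.

    Defaults define the reference conditions used throughout the test
    suite: 200-article sets against a 2,000-article background, a
    500-concept Zipf(1.2) vocabulary, five planted chains at penetrance
    0.1, three injected common terms, and the linking threshold rescaled to
    100 occurrences (the published 150,000 default is expressed against a
    full-scale predication database).
    """

    n_articles_a: int = 200
    n_articles_b: int = 200
    n_background_articles: int = 2000
    n_background_concepts: int = 500
    zipf_exponent: float = 1.2
    planted_chains: list[PlantedChain] = field(default_factory=default_planted_chains)
    n_common_terms: int = 3
    common_term_rate: float = 0.25
    triples_per_article: float = 3.0
    mesh_per_article: float = 2.0
    linking_threshold: int = 100
    bernoulli_planting: bool = False
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_articles_a, self.n_articles_b, self.n_background_articles) <= 0:
            raise ContractError("article counts must be positive")
        if self.n_background_concepts < 10:
            raise ContractError("concept vocabulary too small")
        if self.zipf_exponent <= 0:
            raise ContractError("zipf_exponent must be > 0")
        for chain in self.planted_chains:
            if not (0 < chain.penetrance_a <= 1 and 0 < chain.penetrance_b <= 1):
                raise ContractError(f"penetrance out of (0, 1]: {chain}")
        planted_ids = [c.subject for c in self.planted_chains]
        planted_ids += [c.link for c in self.planted_chains]
        planted_ids += [c.object for c in self.planted_chains]
        if len(planted_ids) != len(set(planted_ids)):
            raise ContractError("planted concept identifiers must be distinct")


@dataclass
class GroundTruth:
    """What was planted, where, and which linking terms are above-cap."""

    planted_chains: list[PlantedChain]
    placements: dict[str, list[int]]  # "s|P1|x|P2|o:A" -> article IDs
    common_terms: list[str]           # injected terms at/above the linking cap
    decoy_chains: list[tuple]         # chains through common terms (5-tuples)

    def planted_identities(self) -> set[tuple]:
        return {c.identity() for c in self.planted_chains}

    def to_json(self) -> dict:
        return {
            "planted_chains": [list(c.identity()) + [c.penetrance_a, c.penetrance_b]
                               for c in self.planted_chains],
            "placements": self.placements,
            "common_terms": self.common_terms,
            "decoy_chains": [list(c) for c in self.decoy_chains],
        }


@dataclass
class SyntheticCorpus:
    """In-memory corpus plus ground truth; files on demand."""

    predications: list[Predication]
    mesh_annotations: list[MeshAnnotation]
    mesh_tree: MeshTree
    pmids_a: list[int]
    pmids_b: list[int]
    truth: GroundTruth
    config: CorpusConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "predications": out / "predications.tsv",
            "mesh_annotations": out / "mesh_annotations.tsv",
            "mesh_tree": out / "mesh_tree.tsv",
            "set_a": out / "set_a.pmids",
            "set_b": out / "set_b.pmids",
            "ground_truth": out / "ground_truth.json",
        }
        write_predications(self.predications, paths["predications"])
        write_mesh_annotations(self.mesh_annotations, paths["mesh_annotations"])
        write_mesh_tree(self.mesh_tree, paths["mesh_tree"])
        write_pmid_list(self.pmids_a, paths["set_a"])
        write_pmid_list(self.pmids_b, paths["set_b"])
        paths["ground_truth"].write_text(
            json.dumps(self.truth.to_json(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        return paths


def _concept(index: int) -> tuple[str, str, str]:
    """Background concept (id, name, semtype); rank-1 is the most common."""
    return (
        f"C{1000000 + index}",
        f"background concept {index}",
        SEMTYPES[index % len(SEMTYPES)],
    )


def _plant_count(penetrance: float, n: int) -> int:
    return math.ceil(penetrance * n)


def generate(config: CorpusConfig | None = None) -> SyntheticCorpus:
    """Generate one corpus; byte-identical files for identical configs."""
    config = config or CorpusConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    pmids_a = list(range(1_000_001, 1_000_001 + config.n_articles_a))
    pmids_b = list(range(2_000_001, 2_000_001 + config.n_articles_b))
    pmids_bg = list(range(3_000_001, 3_000_001 + config.n_background_articles))
    all_pmids = pmids_a + pmids_b + pmids_bg

    vocab_p = 1.0 / np.arange(1, config.n_background_concepts + 1) ** config.zipf_exponent
    vocab_p /= vocab_p.sum()
    predicate_names = [p for p, _ in PREDICATES]
    predicate_p = np.array([w for _, w in PREDICATES], dtype=float)
    predicate_p /= predicate_p.sum()

    names: dict[str, str] = {}
    semtypes: dict[str, str] = {}

    def background_concept() -> str:
        index = int(rng.choice(config.n_background_concepts, p=vocab_p)) + 1
        cid, name, semtype = _concept(index)
        names[cid], semtypes[cid] = name, semtype
        return cid

    predications: list[Predication] = []

    def add_triple(article: int, s: str, p: str, o: str) -> None:
        predications.append(
            Predication(
                article_id=article,
                subject_id=s,
                subject_name=names.get(s, s),
                subject_semtype=semtypes.get(s, "aapp"),
                predicate=p,
                object_id=o,
                object_name=names.get(o, o),
                object_semtype=semtypes.get(o, "aapp"),
            )
        )

    # --- background triples in every article -----------------------------
    for article in all_pmids:
        k = int(rng.poisson(config.triples_per_article))
        for _ in range(k):
            subject = background_concept()
            obj = background_concept()
            while obj == subject:
                obj = background_concept()
            predicate = predicate_names[int(rng.choice(len(predicate_names), p=predicate_p))]
            add_triple(article, subject, predicate, obj)

    # --- planted chains ---------------------------------------------------
    placements: dict[str, list[int]] = {}
    for chain in config.planted_chains:
        for cid, label in ((chain.subject, "planted subject"),
                           (chain.link, "planted link"),
                           (chain.object, "planted object")):
            names[cid] = f"{label} {cid}"
            semtypes[cid] = "gngm"
        if config.bernoulli_planting:
            hits_a = [a for a in pmids_a if rng.random() < chain.penetrance_a]
            hits_b = [b for b in pmids_b if rng.random() < chain.penetrance_b]
        else:
            n_a = _plant_count(chain.penetrance_a, config.n_articles_a)
            n_b = _plant_count(chain.penetrance_b, config.n_articles_b)
            hits_a = sorted(rng.choice(pmids_a, size=n_a, replace=False).tolist())
            hits_b = sorted(rng.choice(pmids_b, size=n_b, replace=False).tolist())
        for article in hits_a:
            add_triple(article, chain.subject, chain.predicate_1, chain.link)
        for article in hits_b:
            add_triple(article, chain.link, chain.predicate_2, chain.object)
        key = "|".join(chain.identity())
        placements[f"{key}:A"] = hits_a
        placements[f"{key}:B"] = hits_b

    # --- injected common terms -------------------------------------------
    decoy_chains: list[tuple] = []
    common_candidates: list[str] = []
    for j in range(1, config.n_common_terms + 1):
        common = f"CCOM{j:02d}"
        decoy_subject = f"CDSUB{j:02d}"
        decoy_object = f"CDOBJ{j:02d}"
        names[common] = f"ubiquitous term {j}"
        semtypes[common] = "popg"
        names[decoy_subject] = f"decoy subject {j}"
        names[decoy_object] = f"decoy object {j}"
        semtypes[decoy_subject] = semtypes[decoy_object] = "gngm"
        common_candidates.append(common)

        # enriched decoy triples through the common term, mirroring the
        # planted-chain mechanics so only the frequency cap can remove them
        n_a = _plant_count(0.1, config.n_articles_a)
        n_b = _plant_count(0.1, config.n_articles_b)
        hits_a = sorted(rng.choice(pmids_a, size=n_a, replace=False).tolist())
        hits_b = sorted(rng.choice(pmids_b, size=n_b, replace=False).tolist())
        for article in hits_a:
            add_triple(article, decoy_subject, "ASSOCIATED_WITH", common)
        for article in hits_b:
            add_triple(article, common, "ASSOCIATED_WITH", decoy_object)
        decoy_chains.append(
            (decoy_subject, "ASSOCIATED_WITH", common, "ASSOCIATED_WITH", decoy_object)
        )
        placements[f"{'|'.join(decoy_chains[-1])}:A"] = hits_a
        placements[f"{'|'.join(decoy_chains[-1])}:B"] = hits_b

        # corpus-wide sprinkling pushes the term over the linking cap
        if config.common_term_rate > 0:
            n_sprinkle = max(
                math.ceil(config.common_term_rate * len(all_pmids)),
                config.linking_threshold,
            )
            n_sprinkle = min(n_sprinkle, len(all_pmids))
            sprinkle = sorted(
                rng.choice(all_pmids, size=n_sprinkle, replace=False).tolist()
            )
            for article in sprinkle:
                add_triple(article, common, "PROCESS_OF", background_concept())

    # --- MeSH side: planted descriptors mirror planted links --------------
    mesh_annotations: list[MeshAnnotation] = []
    tree = MeshTree()
    descriptor_vocab = []
    for index in range(1, max(10, config.n_background_concepts // 10) + 1):
        descriptor = f"D{100000 + index}"
        descriptor_vocab.append(descriptor)
        depth = index % 4 + 1
        tree.add(descriptor, ".".join(["C04"] + [f"{100 + i}" for i in range(depth - 1)]))
    descriptor_p = 1.0 / np.arange(1, len(descriptor_vocab) + 1) ** config.zipf_exponent
    descriptor_p /= descriptor_p.sum()

    for article in all_pmids:
        k = int(rng.poisson(config.mesh_per_article))
        for _ in range(k):
            index = int(rng.choice(len(descriptor_vocab), p=descriptor_p))
            mesh_annotations.append(
                MeshAnnotation(
                    article_id=article,
                    descriptor_id=descriptor_vocab[index],
                    descriptor_name=f"background descriptor {index + 1}",
                    is_major=bool(rng.random() < 0.5),
                )
            )

    for i, chain in enumerate(config.planted_chains, start=1):
        descriptor = f"D{900000 + i}"
        tree.add(descriptor, f"C04.{500 + i}.{100 + i}")
        key = "|".join(chain.identity())
        for article in placements[f"{key}:A"] + placements[f"{key}:B"]:
            mesh_annotations.append(
                MeshAnnotation(
                    article_id=article,
                    descriptor_id=descriptor,
                    descriptor_name=f"planted descriptor {i}",
                    is_major=True,
                )
            )

    # which injected terms actually sit at/above the cap in the emitted corpus
    subject_articles: dict[str, set[int]] = {}
    object_articles: dict[str, set[int]] = {}
    for p in predications:
        subject_articles.setdefault(p.subject_id, set()).add(p.article_id)
        object_articles.setdefault(p.object_id, set()).add(p.article_id)
    common_terms = [
        c
        for c in common_candidates
        if len(subject_articles.get(c, ())) + len(object_articles.get(c, ()))
        >= config.linking_threshold
    ]

    truth = GroundTruth(
        planted_chains=list(config.planted_chains),
        placements=placements,
        common_terms=common_terms,
        decoy_chains=decoy_chains,
    )
    return SyntheticCorpus(
        predications=predications,
        mesh_annotations=mesh_annotations,
        mesh_tree=tree,
        pmids_a=pmids_a,
        pmids_b=pmids_b,
        truth=truth,
        config=config,
    )


@dataclass
class RecoveryReport:
    recall: float
    precision: float
    rank_of_planted: list[int]
    n_reported: int
    common_terms_reported: list[str]


def evaluate_recovery(chains, truth: GroundTruth) -> RecoveryReport:
    """Score reported chains against the planted ground truth.

    Chain identity is the 5-tuple of concept IDs and predicates. Ranks are
    1-based positions in the score ordering. An empty report has recall 0
    and, by convention, precision 1 (no false claims).
    """
    from .ranking import order_results

    ordered = list(order_results(list(chains), "score"))
    reported = [c.identity() for c in ordered]
    planted = truth.planted_identities()
    found = planted & set(reported)
    recall = len(found) / len(planted) if planted else 1.0
    precision = (
        sum(1 for identity in reported if identity in planted) / len(reported)
        if reported
        else 1.0
    )
    ranks = [i for i, identity in enumerate(reported, start=1) if identity in planted]
    common = sorted(
        {c.shared_id for c in ordered if c.shared_id in set(truth.common_terms)}
    )
    return RecoveryReport(
        recall=recall,
        precision=precision,
        rank_of_planted=ranks,
        n_reported=len(reported),
        common_terms_reported=common,
    )
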