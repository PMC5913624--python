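"""Term/triple enrichment: Fisher's exact test, BH correction, caching.

For every key occurring in an article set, a disjoint 2x2 table is built
against the rest of the article universe and tested with a two-tailed
Fisher's exact test. P-values are corrected per (set, method) family with
the Benjamini-Hochberg step-up procedure and thresholded at ``alpha``
(default 1e-5). Results are cached on disk keyed by store fingerprint, set
membership, method and alpha, so repeated comparisons skip the expensive
testing step.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ContractError
from .io import format_float
from .sets import METHODS, ArticleSet, occurrences
from .store import KnowledgeStore, TripleKey

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 1e-5

CACHE_VERSION = "1"


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-tailed Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns ``(p, odds_ratio)``. The two-sided P sums the probabilities of
    all tables with the observed margins whose hypergeometric mass does not
    exceed the observed table's (with a small relative tie tolerance). The
    odds ratio is the sample ratio ``a*d / (b*c)``, with ``inf`` when
    ``b*c == 0``.
    """
    for cell in (a, b, c, d):
        if cell < 0:
            raise ContractError(f"negative contingency cell: {(a, b, c, d)}")
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    odds_ratio = math.inf if b * c == 0 else (a * d) / (b * c)
    return min(p, 1.0), odds_ratio


def bh_correct(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted P-values, in input order.

    ``adjusted_i = min over j >= i of (m * p_(j) / j)`` on the ascending
    sort, clipped to 1 and mapped back to the original positions.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ContractError("P-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    m = p.size
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    adjusted = np.empty(m, dtype=float)
    adjusted[order] = adjusted_sorted
    return adjusted.tolist()


@dataclass(frozen=True, slots=True)
class EnrichmentRecord:
    """One tested key with its contingency counts and test results."""

    key: str | TripleKey
    uniq: int          # member articles containing the key (cell a)
    global_count: int  # background frequency of the key over the whole store
    p: float
    p_corrected: float
    odds_ratio: float


@dataclass
class EnrichmentResult:
    """All tested keys for one (set, method), plus the surviving subset."""

    set_name: str
    method: str
    alpha: float
    n_members: int
    records: list[EnrichmentRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    from_cache: bool = False

    @property
    def surviving(self) -> list[EnrichmentRecord]:
        return [r for r in self.records if r.p_corrected < self.alpha]

    def surviving_keys(self) -> set[str | TripleKey]:
        return {r.key for r in self.surviving}


def _contingency(
    uniq: int, global_count: int, n_members: int, n_universe: int
) -> tuple[int, int, int, int]:
    """Disjoint 2x2: set members vs the rest of the article universe."""
    a = uniq
    b = n_members - a
    c = global_count - a
    d = n_universe - n_members - c
    return a, b, c, d


def _key_str(key: str | TripleKey) -> str:
    if isinstance(key, tuple):
        return "\t".join(key)
    return key


def enrich(
    store: KnowledgeStore,
    article_set: ArticleSet,
    method: str,
    alpha: float = DEFAULT_ALPHA,
    cache_dir: str | Path | None = None,
) -> EnrichmentResult:
    """Test every key of the set's occurrence table against the background.

    With ``cache_dir`` set, a result computed earlier for the identical
    (store, set membership, method, alpha) is loaded from disk instead of
    recomputed; a fingerprint mismatch triggers recomputation with a
    warning, never silent reuse.
    """
    if method not in METHODS:
        raise ContractError(f"unknown method {method!r}")
    if not (0 < alpha <= 1):
        raise ContractError(f"alpha must be in (0, 1]: {alpha}")

    cache_base = None
    if cache_dir is not None:
        cache_base = _cache_base(Path(cache_dir), store, article_set, method, alpha)
        cached = _load_cache(cache_base, store, article_set, method, alpha)
        if cached is not None:
            logger.info("cache hit for set=%s method=%s", article_set.name, method)
            cached.from_cache = True
            return cached

    counts = occurrences(store, article_set, method)
    if method == "triple":
        background = store.global_triple_freq
    elif method == "concept":
        background = store.concept_article_freq
    else:
        background = store.global_mesh_freq

    keys = sorted(counts, key=_key_str)
    pvalues: list[float] = []
    odds: list[float] = []
    for key in keys:
        table = _contingency(
            counts[key], background[key], article_set.n_members, store.n_articles
        )
        p, odds_ratio = fisher_two_tailed(*table)
        pvalues.append(p)
        odds.append(odds_ratio)
    adjusted = bh_correct(pvalues)

    records = [
        EnrichmentRecord(
            key=key,
            uniq=counts[key],
            global_count=background[key],
            p=p,
            p_corrected=p_adj,
            odds_ratio=odds_ratio,
        )
        for key, p, p_adj, odds_ratio in zip(keys, pvalues, adjusted, odds)
    ]
    result = EnrichmentResult(
        set_name=article_set.name,
        method=method,
        alpha=alpha,
        n_members=article_set.n_members,
        records=records,
        metadata={
            "counting": "distinct-articles (set and background)",
            "background": "disjoint (set excluded)",
            "store_fingerprint": store.fingerprint,
            "set_member_hash": article_set.member_hash(),
            "n_universe": store.n_articles,
        },
    )
    if cache_base is not None:
        _write_cache(cache_base, result)
    return result


# ----------------------------------------------------------------- caching

def _cache_base(
    cache_dir: Path,
    store: KnowledgeStore,
    article_set: ArticleSet,
    method: str,
    alpha: float,
) -> Path:
    import hashlib

    token = "\n".join(
        [store.fingerprint, article_set.member_hash(), method, format_float(alpha)]
    )
    digest = hashlib.sha256(token.encode()).hexdigest()[:24]
    cache_dir.mkdir(parents=True, exist_ok=True)
    return cache_dir / f"enrich-{digest}"


def _manifest(result: EnrichmentResult) -> dict:
    return {
        "cache_version": CACHE_VERSION,
        "set_name": result.set_name,
        "method": result.method,
        "alpha": format_float(result.alpha),
        "n_members": result.n_members,
        "store_fingerprint": result.metadata["store_fingerprint"],
        "set_member_hash": result.metadata["set_member_hash"],
        "n_universe": result.metadata["n_universe"],
        "counting": result.metadata["counting"],
        "background": result.metadata["background"],
    }


def _write_cache(base: Path, result: EnrichmentResult) -> None:
    lines = ["key\tuniq\tglobal\tp\tp_corrected\todds_ratio"]
    for r in result.records:
        lines.append(
            "\t".join(
                [
                    _key_str(r.key).replace("\t", "|"),
                    str(r.uniq),
                    str(r.global_count),
                    format_float(r.p),
                    format_float(r.p_corrected),
                    format_float(r.odds_ratio),
                ]
            )
        )
    base.with_suffix(".tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    base.with_suffix(".manifest.json").write_text(
        json.dumps(_manifest(result), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def _load_cache(
    base: Path,
    store: KnowledgeStore,
    article_set: ArticleSet,
    method: str,
    alpha: float,
) -> EnrichmentResult | None:
    table = base.with_suffix(".tsv")
    manifest_path = base.with_suffix(".manifest.json")
    if not table.exists() or not manifest_path.exists():
        return None
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    if manifest.get("store_fingerprint") != store.fingerprint:
        logger.warning(
            "cache %s was built against a different store; recomputing", base.name
        )
        return None
    if (
        manifest.get("set_member_hash") != article_set.member_hash()
        or manifest.get("method") != method
        or manifest.get("alpha") != format_float(alpha)
    ):
        return None

    records: list[EnrichmentRecord] = []
    lines = table.read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        key_s, uniq, global_count, p, p_adj, odds_ratio = line.split("\t")
        key: str | TripleKey = (
            tuple(key_s.split("|")) if method == "triple" else key_s
        )
        records.append(
            EnrichmentRecord(
                key=key,
                uniq=int(uniq),
                global_count=int(global_count),
                p=float(p),
                p_corrected=float(p_adj),
                odds_ratio=float(odds_ratio),
            )
        )
    return EnrichmentResult(
        set_name=manifest["set_name"],
        method=method,
        alpha=alpha,
        n_members=manifest["n_members"],
        records=records,
        metadata={
            "counting": manifest["counting"],
            "background": manifest["background"],
            "store_fingerprint": manifest["store_fingerprint"],
            "set_member_hash": manifest["set_member_hash"],
            "n_universe": manifest["n_universe"],
        },
    )
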