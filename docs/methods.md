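# Methods

## Data model

The corpus is indexed from two tables. A *predication* is one extracted
subject–PREDICATE–object triple attributed to one article; a *MeSH
annotation* assigns one descriptor to one article with a major-topic flag.
Evidence is deduplicated to (article, triple) and (article, descriptor)
pairs at indexing time: the unit of evidence everywhere is the distinct
article, never the mention, so a concept repeated ten times in one abstract
carries the same weight as a single mention. Concept identity is the
subject/object identifier string (CUI-like); names and semantic types are
display attributes only. Triple keys are directed — (x, P, y) and (y, P, x)
are different keys.

The article universe is the union of article IDs seen in either input
table. Articles the corpus never saw are invisible; uploaded set IDs are
intersected with coverage and the number of absent IDs is reported. All
contingency denominators use covered members only, so unannotated uploads
cannot dilute the statistics.

Two frequency notions coexist for concepts. `concept_article_freq` counts
distinct articles containing the concept in either slot and is the
background unit for enrichment 2×2 tables. `concept_occurrence_freq` counts
(article, slot) pairs — an article contributes once as subject-context and
once as object-context — and is the scale on which the linking-term
frequency cap is expressed (published full-scale caps are occurrence
counts, not article counts). Which count backs the enrichment table is
recorded in the result metadata.

## Enrichment

For each key occurring in a set of *n* members, the 2×2 table is
*a* = distinct members with the key, *b* = *n* − *a*, *c* = *g* − *a*,
*d* = *N* − *n* − *c*, with *g* the key's global distinct-article count and
*N* the universe size. The set is excluded from the background side: a
disjoint table is the standard exact-test formulation, and it makes the
degenerate case transparent (testing the full store against itself gives
*c* = *d* = 0 and *P* = 1 for every key).

The test is the conventional two-sided Fisher's exact test — the sum of the
probabilities of all tables with the observed margins whose hypergeometric
mass does not exceed the observed table's, with a 1e-7 relative tie
tolerance (`scipy.stats.fisher_exact`; the test suite checks it against an
exhaustive rational-arithmetic enumeration oracle to 1e-10 absolute).
The odds ratio is the unconditional sample ratio *ad/bc*, reported as ∞
whenever *bc* = 0.

Benjamini–Hochberg correction is applied within one (set, method) family —
never across sets or methods, since downstream summaries average corrected
P-values *across* the two sets. The step-up form is implemented directly
(adjusted_i = min over j ≥ i of m·p₍ⱼ₎/j on the ascending sort, clipped to
1) so its float semantics are pinned exactly; `statsmodels`' `fdr_bh` is
used as an independent cross-check in the tests. Keys with *a* = 1 are
tested rather than pre-excluded: at realistic corpus sizes a single
supporting article cannot reach corrected *P* < 1e-5, so the cutoff
performs that exclusion naturally, while very small sets legitimately keep
it possible.

The default cutoff is corrected *P* < 1e-5 (strict inequality). Enrichment
results are serialized to a per-(set, method) cache file keyed by a SHA-256
store fingerprint, the set-membership hash, method and alpha; a fingerprint
mismatch always recomputes with a warning. Cache tables are written with
deterministic key ordering and shortest round-trip float formatting, so a
cache hit is byte-identical to the original computation.

## Chaining and the linking-term cap

Triple overlap takes the two surviving enrichment lists and emits one chain
per pair of enriched triples (s, P1, x) ∈ A and (x, P2, o) ∈ B sharing the
linking concept x. Direction is strict — A-objects join B-subjects only —
reflecting the convention that set A is the exposure side; reversing the
roles of the sets generally yields a different chain set, and chains
supported only in the reverse direction never appear. Some predicates are
semantically symmetric (PART_OF, ASSOCIATED_WITH), and no symmetry
expansion is attempted; users who want both directions run the comparison
both ways.

The linking term must satisfy occurrence(x) < threshold (default 150,000,
the full-scale value; synthetic corpora rescale it — the generator default
is 100). The cap applies only to the linking position, never to outer
subjects or objects, and is deliberately the only predicate-independent
pruning: all predicates are kept because sparse overlaps may only be
expressed through common relations like ASSOCIATED_WITH. Relaxing the
threshold can only enlarge the chain set (monotonicity, property-tested).

Provenance is attached by intersecting each side's triple inverted index
with the set membership; the resulting ID lists must have exactly the
lengths recorded as uniq_a/uniq_b at enrichment time, and a mismatch raises
an internal-consistency error rather than silently disagreeing.

## Ranking and filtering

The balance score min/max × (sum) over (uniq_a, uniq_b) is the default
ordering; mean corrected P (ascending), minimum-position MeSH depth
(deepest first) and predicate frequency rank (rarest first, using the
minimum of the two predicate ranks) are alternatives. Predicate ranks are
global-frequency ranks with rank 1 the most frequent; ties break
alphabetically so ranks are a deterministic permutation. All orderings
break residual ties by total support descending and then the lexicographic
identity tuple, making every ordering total and reproducible.

Filters apply in a fixed order — corrected-P, odds ratio (both sides must
pass, i.e. min of the two), PFR/MeSH-depth, keywords, top-N — with survivor
counts recorded per stage. Keyword matching is case-insensitive substring
on any of the five chain positions (exact-match mode by flag); include
lists mean "keep rows matching at least one keyword at that position". The
corrected-P filter threshold is inclusive (≤), matching filter-panel
semantics, while the enrichment alpha itself is strict (<).

First-pass display rules are size-adaptive: ≤ 50 results pass through
unfiltered; up to 1,000 keep the top 100 by score; beyond that the five
globally most frequent predicates are also excluded (min_pfr = 6). The
50/1000/100/5 parameterization is this package's choice for behaviour that
is qualitative in origin ("relax the filters when results are few"); all
four numbers are module constants surfaced in run metadata.

Sequential application of two filter panels equals a single stricter
combined panel (`combine_specs`) for all threshold fields and exclude
lists; include lists at the *same* position compose conjunctively when
applied sequentially, which a single panel's disjunctive include list
cannot express — the combined panel unions them, which is the closest
single-panel equivalent.

## Synthetic corpora

The generator emulates what the engine assumes about real literature:

* background triples whose concepts follow a Zipf law (exponent 1.2 over a
  500-concept vocabulary by default) — a few near-ubiquitous concepts and a
  long tail, matching the shape of concept-frequency distributions in
  predication databases;
* a predicate vocabulary with strongly skewed frequencies, so predicate
  ranks behave as they do at full scale;
* planted chains (default: five, penetrance 0.1) whose two triples are
  placed in exactly ⌈penetrance × n⌉ distinct set articles — deterministic
  placement keeps the planted contingency tables exact so statistical tests
  of the engine are not confounded by sampling noise (a Bernoulli mode
  exists for power studies);
* injected common terms that form enriched decoy chains *and* are sprinkled
  corpus-wide until their occurrence count reaches the linking cap, so only
  the frequency filter — not the enrichment — can remove them;
* a MeSH side mirroring the planted links (one major descriptor per planted
  chain in the same articles), so all three methods are testable from one
  corpus.

Default sizes are 200 + 200 set articles against 2,000 background articles
with ~3 triples and ~2 annotations per article and the linking threshold
rescaled to 100 occurrences. These sizes keep a full 20-seed recovery study
under a minute while leaving planted support (20 articles per side) an
order of magnitude above what chance produces for any background triple.

What the generator does **not** emulate: extraction errors and negation,
synonymy/CUI drift, per-journal annotation depth, citation structure and
publication dates, and correlated topic drift between the two sets. Passing
recovery tests therefore show the engine's statistics and chaining are
correct under its own assumptions, not that real predication data meet
those assumptions.

## Numerical and degenerate-input choices

* Fisher P-values are clipped to [0, 1]; a table with an all-zero row or
  column has P = 1.
* Odds ratio ∞ is serialized as `inf` in TSV and `Infinity` in JSON
  (Python JSON round-trips it).
* Floats are serialized with `repr` (shortest round-trip), so re-reading a
  cache or result file reproduces exact values and repeated runs are
  byte-identical.
* Empty enrichment input (a set whose members carry no keys for a method)
  yields an empty result, not an error; empty filter output is valid.
* Unknown MeSH descriptors have depth `None` and are rejected by the
  depth ordering rather than sorted arbitrarily.
* Rows with unparseable article IDs are dropped and counted, never
  silently coerced.

## Limitations

Chains are single-step (A→X→B); longer paths are only discoverable
visually in the network export. Non-major MeSH annotations are stored but
never counted for enrichment. The engine consumes pre-extracted
predications and annotations; no text processing or network retrieval is
performed. Set-size extremes matter: for very small sets the 1e-5 cutoff is
conservative, and single-article evidence can reach significance only when
the corpus is tiny.
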