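# litmech

Literature-based discovery of mechanistic intermediates between two
biomedical concepts.

Given two article sets — one gathered around an exposure or risk factor
(set A), one around an outcome (set B) — `litmech` finds the annotation
objects statistically over-represented in each set relative to the whole
corpus, and chains them into candidate mechanisms. It works on three kinds
of literature annotation:

* **MeSH descriptors** (major-topic annotations of each article),
* **extracted concepts** (the subjects/objects of subject–PREDICATE–object
  predications, as produced by semantic-predication extraction pipelines),
* **whole triples**, which are chained across the two sets: every enriched
  triple *(s, P1, x)* of set A whose object *x* is the subject of an
  enriched triple *(x, P2, o)* of set B yields a candidate mechanism
  *s —P1→ x —P2→ o*, with full per-side publication provenance.

This is the ABC discovery pattern: if the A-literature links *s* to *x*,
and the B-literature links *x* to *o*, then *x* is a candidate intermediate
even when no single article mentions both ends.

## The statistics

For each key (descriptor, concept or triple) occurring in an article set of
size *n*, a disjoint 2×2 table is formed against the rest of the indexed
corpus (*N* articles):

|                | has key | lacks key  |
|----------------|---------|------------|
| set members    | *a*     | *n − a*    |
| other articles | *g − a* | *N − n − (g − a)* |

where *a* counts **distinct** member articles containing the key (repeated
mentions inside one abstract never count twice) and *g* is the key's global
distinct-article frequency. The table is tested with a two-tailed Fisher's
exact test; P-values are Benjamini–Hochberg corrected within each
(set, method) family and thresholded at corrected *P* < 1e-5. The sample
odds ratio *ad/bc* is reported alongside (∞ when *bc* = 0).

Chained triples pass one further filter: the linking term *x* must occur
fewer than 150,000 times globally (configurable; counted as
(article, subject/object-slot) occurrences). This removes ubiquitous
concepts such as "Patients" or "Cells" that would otherwise connect
everything to everything.

Overlapping elements are ranked by a balance score over the per-side
unique-article support counts

```
score = min(uniq_a, uniq_b) / max(uniq_a, uniq_b) × (uniq_a + uniq_b)
```

which prefers intermediates supported by many *and equally many* articles
on both sides: (5, 5) → 10 outranks (1, 100) → 1.01. Alternative orderings
(mean corrected P, MeSH hierarchy depth, predicate frequency rank) and an
interactive-style filter panel (P/odds-ratio thresholds, keyword
filter/restrict on any of the five chain positions, top-N) are provided.

## Worked example

The package ships a synthetic-corpus generator that emulates the inputs:
Zipf-distributed background concepts, planted A→X→B mechanisms at known
penetrance, and injected above-cap common terms. The whole pipeline from
the shell:

```
litmech simulate --out corpus --seed 7
litmech build-store --predications corpus/predications.tsv \
    --mesh corpus/mesh_annotations.tsv --tree corpus/mesh_tree.tsv \
    --out store.db
litmech create-set --store store.db --name exposure \
    --pmids corpus/set_a.pmids --out setA.json
litmech create-set --store store.db --name outcome \
    --pmids corpus/set_b.pmids --out setB.json
litmech overlap --store store.db --set-a setA.json --set-b setB.json \
    --method triple --linking-threshold 100 --out chains.json
litmech filter --results chains.json --max-p 1e-5 --top 10 \
    --order score --out top.json
litmech export --results top.json --format tsv --out results.tsv
```

which prints

```
9359 predications, 4936 annotations, 5 planted chains -> corpus
store: 2395 articles, 5195 distinct triples
set 'exposure': 200 members (0 requested IDs not in store)
set 'outcome': 199 members (1 requested IDs not in store)
5 overlapping elements
5 rows after filtering (stages: [('input', 5), ('max_mean_p_corrected', 5),
  ('min_odds_ratio', 5), ('pfr_depth', 5), ('keywords', 5), ('top_n', 5)])
wrote tsv document with 5 result rows
```

All five planted mechanisms — and nothing else — survive: each chain row in
`results.tsv` carries the planted subject/link/object, 20 supporting
articles per side (penetrance 0.1 × 200 members), balance score 40.0, and
the supporting PubMed IDs per side. The three injected common terms are
absent: their global occurrence counts exceed the linking threshold of 100.
`--format network` and `--format sankey` export the same results as
renderer-agnostic JSON graph documents whose link weights equal the
supporting-publication counts.

The same pipeline is available as a library (`litmech.discover_chains`,
`litmech.discover_shared_terms`), and real predication/MeSH dumps can be
used by converting them to the documented TSV dialects (columns bind by
name, see `litmech.io`).

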