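# Methods

## Pipeline overview

The package turns per-document standoff annotations into an
evidence-weighted directed multigraph in four stages:

1. **Parsing** (`annotation_io`) — brat-compatible `T`/`R`/`A` records, one
   file per abstract, with 0-based half-open character offsets. Polarity
   resolution order: an explicit `A`-line polarity attribute overrides the
   schema's per-type default (benefits/increases → beneficial,
   reduces/inhibits/harms → harmful, the other seven types → neutral).
   Malformed lines are hard errors with line numbers; vocabulary violations
   are collected per document (or raised in strict mode) so one bad
   annotation does not discard an abstract.
2. **Consolidation** (`consolidation`) — labels are lexically normalized
   (case-folded, whitespace-collapsed, a single trailing parenthetical of at
   most 10 characters stripped — long parenthetical groups are preserved to
   protect chemical names) and then looked up in an expert-curated synonym
   table. Matching is exact on the lexically normalized string, never fuzzy:
   every merge must have been reviewed. The table is validated against
   variant conflicts and chains at load time. A mention counts as *unified*
   only when the table changed its label beyond lexical normalization, so
   case fixes do not inflate the consolidation statistics; a consequence is
   that applying consolidation twice leaves the corpus unchanged and the
   second report correctly counts zero new merges.
3. **Aggregation and weighting** (`graph_builder`) — one edge per unique
   (source, target, relation type) triple. The evidence frequency *F*
   counts *distinct* supporting documents; the total instance count is kept
   separately for provenance. The weight is `W = ln(F+1) × P` with
   multipliers 1.2/1.1/1.0. The natural logarithm is intrinsic to the
   definition: the characteristic reported weights (2.30 at F = 9 neutral,
   1.93 at F = 4 beneficial, 0.693 at F = 1 neutral, …) arise only under
   base *e*. When merged instances disagree on polarity the majority wins
   and exact ties resolve to neutral (conflicts are logged); the edge key
   deliberately excludes polarity so each triple has one polarity.
   Self-loops created by consolidation are dropped. Edges keep annotation
   direction; nothing is symmetrized, so stage-ordered chain traversal stays
   meaningful. Pruning of relation-free entities is implicit: nodes exist
   only as edge endpoints. A node's category is the majority category over
   its mentions, ties broken alphabetically for determinism.
4. **Analysis** — topology, pathway evidence, and coverage benchmarking
   (below).

## Topology conventions

Degree and weighted degree are incident-edge counts/sums on the directed
multigraph (in + out), which is how hub connectivity is conventionally
reported for this kind of graph. Clustering and density are classical
undirected quantities, so they are computed on the undirected *simple*
projection (parallel and antiparallel edges collapse to one link):
density = E/(N(N−1)/2) and the mean local clustering coefficient averages
over **all** nodes, with degree-<2 nodes contributing 0 — a convention that
must be fixed for the mean to be well defined, and stated in the report
header. Clustering is unweighted; whether a weighted variant is preferable
is an open modelling choice, and the unweighted choice is flagged in the
report. Hub ranking is stable-descending with lexicographic tie-breaks. The
category-connectivity matrix counts edges per ordered category pair, then
symmetrizes off-diagonal cells by summing with their transpose (the diagonal
keeps its raw count — summing it with itself would double-count);
normalization is by global maximum (default) or per row.

## Pathway evidence

Node–keyword matching is case-insensitive whole-word containment (or exact
equality), not free substring: "butyrate" matches "butyrate production" but
not "butyrogenesis", and "art" does not match "heart". An edge supports a
pathway when both endpoints match some stage's keywords and a stage
assignment exists with source stage ≤ target stage (same-stage links
allowed). Evidence is reported as unique supporting documents (union over
matched edges) and relation *instances* (sum of instance counts) — instances
rather than unique edges, since one abstract often states the same link more
than once and the instance count is the transparent measure of annotation
support; this semantics is recorded in the report metadata. Chain
enumeration performs a DFS over simple directed paths that start at a
first-stage match, end at a last-stage match, and visit stages
non-decreasingly (skips allowed), capped at 6 nodes by default to bound the
combinatorics. Up/down arrows in chain renderings derive from the hop's
relation type (increases/benefits → ↑, reduces/inhibits/harms → ↓).

## Coverage benchmarking

Marker detection reuses the whole-word rule, extended by per-marker synonym
lists, because database nomenclature ("butanoate") rarely matches literature
surface forms ("butyrate") verbatim. Entity coverage is
`M_detected/M_total × 100`; edge coverage `R_found/R_expected × 100`, with
expected-edge direction respected by default and an undirected option.
Percentages are rounded half-up to one decimal (`decimal`-based, since
Python's built-in rounding is banker's). The marker sets shipped by the
generator are synthetic stand-ins constructed to exercise the machinery;
they name real KEGG/Reactome identifiers only as illustrative external
references and are not curated pathway content.

## Synthetic study conditions

The generator (`synthetic_corpus`) emulates the statistical features of a
manually annotated literature corpus at desk scale. Defaults, chosen once as
a realistic scaled-down corpus:

- 120 documents; 300 background ("distractor") edges, each a unique
  frequency-1 triple over a disjoint label namespace, with polarity drawn
  from the literature mix 62.6% neutral / 23.1% beneficial / 14.3% harmful;
- 13 planted triples with frequencies spanning 1–9 distinct documents
  (document assignment is uniform sampling without replacement), including
  a five-edge "gut microbiota" hub, one triple with a duplicate
  within-document instance (so instance count exceeds frequency), and two
  four-stage mechanistic chains — a beneficial fiber→Faecalibacterium→
  butyrate→inflammation axis and a harmful western-diet→dysbiosis→LPS→
  insulin-resistance cascade whose `increases`/`causes` hops carry explicit
  harmful polarity attributes;
- three lexical-variant groups (gut microbiota, short-chain fatty acids,
  mediterranean diet) substituted deterministically into mention surfaces;
- 15 isolated mentions that graph construction must prune;
- five marker sets mixing planted labels with deliberately absent markers,
  giving known entity and edge coverages.

All randomness flows through a single seeded `numpy` generator; identical
spec and seed give byte-identical corpora. Mention spans are synthesized
from a template sentence per relation — they satisfy the format invariants
but are not linguistically realistic, and no abstract text is generated.
Consequently, passing tests demonstrate correctness of the *pipeline
mechanics* (parsing, consolidation, aggregation arithmetic, matching,
coverage) under known ground truth; they say nothing about annotation
quality, annotator disagreement, or retrieval bias in real corpora, and the
original corpus-scale statistics (thousands of entities, clustering ≈ 0.6,
hub degrees in the hundreds) are not reproduced here because that corpus is
not deposited.

A fixed 12-document regression fixture (`regression_fixture`) complements
the randomized generator: its expectations (30 mentions, 8 unique edges, 8
table-unified mentions into 3 normalized forms, a 1–1 polarity conflict
resolving to neutral, pathway support of 5 docs/6 rels and 3 docs/4 rels)
were counted by hand and are frozen alongside the fixture.

## Numerical and degenerate-input choices

- Weights are exact floats; reports round half-up to 2–3 decimals.
- `compute_edge_weight` rejects F < 1: an edge cannot exist without
  evidence.
- Density is undefined (error) below 2 nodes; an empty keyword list is an
  error, while keywords that match nothing yield zero metrics.
- Duplicate document ids abort corpus loading; per-file parse failures are
  collected in non-strict mode.
- All tabular outputs are sorted, making every artifact byte-reproducible
  for a fixed input, configuration, and seed; reports embed the package
  version and a configuration hash.

## Known limitations

- Category names beyond those evidenced in practice are configuration
  placeholders; the schema file is the authority.
- Indexed per-type edge labels (e.g. `affects_1`) are reproduced as
  same-type edges ranked by weight; no external mapping exists to verify
  specific entity pairs.
- No community detection, link prediction, or ontology alignment; the
  graph is static and polarity conflicts are resolved, not modelled.
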