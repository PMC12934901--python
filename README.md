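# dmhkg — evidence-weighted diet–microbiome–health knowledge graphs

`dmhkg` builds and analyses polarity-aware knowledge graphs of
diet–microbiome–health mechanisms from manually annotated literature
abstracts. It is aimed at researchers in nutrition science and microbiome
systems biology who have (or are curating) standoff-style entity/relation
annotations of PubMed abstracts and want a transparent, reproducible route
from those annotations to a weighted mechanistic network with quantitative
validation.

## The model

Annotations use a schema of 11 entity categories (nutrition, microbiome,
metabolite, disease, …) and 12 directional relation types
(`associated_with`, `affects`, …, `benefits`, `increases`, `reduces`,
`inhibits`, `harms`), each relation instance carrying a polarity label —
*beneficial*, *harmful*, or *neutral*. After expert-curated synonym
consolidation, every unique (source, target, relation type) triple becomes
one directed edge with composite evidence weight

```
W = ln(F + 1) × P
```

where *F* is the number of distinct abstracts supporting the triple
(log-damped so high-frequency associations do not dominate) and *P* is the
polarity multiplier: 1.2 beneficial, 1.1 harmful, 1.0 neutral. Entities
participating in no relation are pruned. On top of the graph the package
computes:

- **Topology** — degree and weighted degree (incident edges, in + out),
  hub ranking, mean local clustering and density on the undirected simple
  projection, per-category degree summaries, and the normalized
  category-connectivity matrix.
- **Pathway evidence (internal validation)** — keyword-defined mechanistic
  pathways over ordered stages Diet → Microbiome → Metabolite → Outcome,
  scored by unique supporting documents and relation instances, with
  enumeration of stage-ordered mechanistic chains.
- **Coverage benchmarking (external validation)** — against curated marker
  sets (e.g. from KEGG/Reactome pathways): entity coverage
  `C_entity = M_detected / M_total × 100` and edge coverage
  `C_edge = R_found / R_expected × 100`.

Because corpora of this kind are rarely depositable, the package ships a
first-class synthetic-corpus generator (`dmhkg.synthetic_corpus`) that
emulates the statistical structure of such a corpus — per-triple evidence
frequencies of 1–9 unique abstracts, a 62.6/23.1/14.3 neutral/beneficial/
harmful polarity mix, lexical variant fragmentation, isolated mentions, and
planted multi-stage chains — together with a ground-truth manifest that
every pipeline stage is tested to recover exactly.

## Worked example

```
$ dmhkg simulate --out demo/sim --seed 42
simulated corpus: 120 documents, 723 mentions, 354 relations -> demo/sim/corpus
$ dmhkg build --corpus demo/sim/corpus --synonyms demo/sim/synonyms.tsv --out demo/graph
built graph: 618 nodes, 313 edges -> demo/graph
$ dmhkg pathways --graph demo/graph --definitions demo/sim/pathways.json --out demo/pw
$ cat demo/pw/pathway_evidence.tsv
pathway	polarity	docs	rels	n_chains	chain
Fiber-Faecalibacterium-Butyrate-Inflammation	beneficial	12	13	1	whole grain fiber → faecalibacterium prausnitzii ↑ → butyrate ↑ → gut inflammation ↓
Western diet-Dysbiosis-LPS-Insulin resistance	harmful	9	9	1	western diet → gut dysbiosis → endotoxin lps ↑ → insulin resistance ↑
```

The 120-document corpus contains two planted four-stage chains; the
beneficial fiber→butyrate axis is recovered with 12 unique supporting
documents and 13 relation instances (one document annotates the first hop
twice, which is why instances exceed documents), and the arrows render each
hop's polarity. Coverage benchmarking against the five packaged synthetic
marker sets then reports, per pathway, strings like `80.0% (4/5)` entity
coverage and `75.0% (3/4)` edge coverage plus the unweighted mean:

```
$ dmhkg benchmark --graph demo/graph --markers demo/sim/markers --out demo/bench
benchmark (5 pathways) -> demo/bench/benchmark.tsv
```

In Python, the weighting function itself:

```python
>>> from dmhkg import compute_edge_weight
>>> round(compute_edge_weight(9, "neutral"), 2)   # 9 abstracts, neutral
2.3
>>> round(compute_edge_weight(4, "beneficial"), 2)
1.93
```

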