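"""Synthetic annotated corpora with ground-truth manifests.

The real annotated corpus behind this kind of knowledge graph is typically
not depositable, so every pipeline stage must be testable against data whose
true structure is known.  The generator emulates the statistical features
the analysis assumes: per-triple evidence frequencies across unique
abstracts (range ~1-9), a three-class polarity mix for background edges
(~62.6/23.1/14.3), lexical variant fragmentation of entity labels, isolated
(relation-free) mentions, and planted multi-stage
diet -> microbiome -> metabolite -> outcome chains distributed across
documents.  Alongside the corpus it emits a :class:`GroundTruthManifest`
recording every quantity the pipeline should recover exactly.

All randomness flows through one seeded ``numpy`` generator; identical spec
and seed produce byte-identical output.  Mention spans come from a template
sentence per relation — they satisfy the format invariants, not linguistic
realism.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .annotation_io import (
    AnnotatedDocument,
    Corpus,
    EntityMention,
    RelationInstance,
    write_standoff,
)
from .consolidation import SynonymMap, lexical_normalize, write_synonym_table
from .pathway_benchmark import MarkerSet
from .pathway_evidence import PathwayDefinition
from .schema import POLARITY_CLASSES, SchemaConfig

# ---------------------------------------------------------------------------
# spec


@dataclass(frozen=True)
class PlantedEdge:
    """A (source, target, type) triple planted at a target frequency F*."""

    source: str
    target: str
    relation_type: str
    polarity: str
    frequency: int
    extra_instances: int = 0  # duplicate instances in the first chosen doc


@dataclass(frozen=True)
class SyntheticSpec:
    n_documents: int = 120
    planted_edges: tuple[PlantedEdge, ...] = ()
    label_categories: dict[str, str] = field(default_factory=dict)
    polarity_mix: tuple[float, float, float] = (0.626, 0.231, 0.143)
    n_distractor_edges: int = 300
    n_isolated_mentions: int = 15
    variant_table: dict[str, tuple[tuple[str, int], ...]] = field(default_factory=dict)
    pathways: tuple[PathwayDefinition, ...] = ()
    pathway_triples: dict[str, tuple[tuple[str, str, str], ...]] = field(
        default_factory=dict
    )
    marker_sets: tuple[MarkerSet, ...] = ()
    seed: int = 42

    def __post_init__(self) -> None:
        if abs(sum(self.polarity_mix) - 1.0) > 1e-9:
            raise ValueError("polarity mix proportions must sum to 1")
        for e in self.planted_edges:
            if not 1 <= e.frequency <= self.n_documents:
                raise ValueError(
                    f"planted frequency {e.frequency} for {e.source!r}->"
                    f"{e.target!r} outside [1, n_documents]"
                )


@dataclass
class GroundTruthManifest:
    """Everything the pipeline is expected to recover, exactly."""

    n_documents: int
    mentions_total: int
    relations_total: int
    mentions_unified: int
    normalized_forms: int
    n_nodes: int
    n_edges: int
    triples: dict[tuple[str, str, str], dict]
    polarity_edge_counts: dict[str, int]
    pathway_metrics: dict[str, dict]
    marker_coverage: dict[str, dict]

    def to_dict(self) -> dict:
        out = {
            "n_documents": self.n_documents,
            "mentions_total": self.mentions_total,
            "relations_total": self.relations_total,
            "mentions_unified": self.mentions_unified,
            "normalized_forms": self.normalized_forms,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "polarity_edge_counts": self.polarity_edge_counts,
            "pathway_metrics": self.pathway_metrics,
            "marker_coverage": self.marker_coverage,
            "triples": {
                "|".join(key): value for key, value in sorted(self.triples.items())
            },
        }
        return out


@dataclass
class SyntheticCorpusResult:
    corpus: Corpus
    synonym_map: SynonymMap
    manifest: GroundTruthManifest
    pathways: tuple[PathwayDefinition, ...]
    marker_sets: tuple[MarkerSet, ...]
    spec: SyntheticSpec


# ---------------------------------------------------------------------------
# document assembly


class _DocBuilder:
    """Accumulates mentions/relations for one document with running offsets."""

    def __init__(self, doc_id: str):
        self.doc = AnnotatedDocument(doc_id=doc_id)
        self._cursor = 0
        self._mentions = 0
        self._relations = 0

    def add_mention(self, category: str, surface: str) -> str:
        self._mentions += 1
        mid = f"T{self._mentions}"
        start = self._cursor
        end = start + len(surface)
        self.doc.mentions.append(
            EntityMention(
                doc_id=self.doc.doc_id,
                mention_id=mid,
                category=category,
                surface=surface,
                span_start=start,
                span_end=end,
            )
        )
        self._cursor = end + 1  # template separator
        return mid

    def add_relation(
        self, rtype: str, polarity: str, src_mid: str, tgt_mid: str
    ) -> None:
        self._relations += 1
        self.doc.relations.append(
            RelationInstance(
                doc_id=self.doc.doc_id,
                relation_id=f"R{self._relations}",
                relation_type=rtype,
                polarity=polarity,
                source_mention=src_mid,
                target_mention=tgt_mid,
            )
        )
        self._cursor += len(rtype) + 2


class _VariantSubstituter:
    """Hands out planted lexical variants in a fixed order per canonical label."""

    def __init__(
        self, variant_table: dict[str, tuple[tuple[str, int], ...]], options
    ):
        self._queues = {
            canonical: [v for v, count in variants for _ in range(count)]
            for canonical, variants in variant_table.items()
        }
        self._cursor = {canonical: 0 for canonical in self._queues}
        self._options = options
        self.unified = 0
        self.unified_forms: set[str] = set()

    def surface_for(self, canonical: str) -> str:
        queue = self._queues.get(canonical)
        if queue is None:
            return canonical
        i = self._cursor[canonical]
        if i >= len(queue):
            return canonical
        self._cursor[canonical] = i + 1
        variant = queue[i]
        # a substitution counts as "unified" only when it changes the label
        # beyond lexical normalization (mirrors the consolidation semantics)
        if lexical_normalize(variant, self._options) != lexical_normalize(
            canonical, self._options
        ):
            self.unified += 1
            self.unified_forms.add(canonical)
        return variant


# ---------------------------------------------------------------------------
# generation


def generate_corpus(
    spec: SyntheticSpec, schema: SchemaConfig | None = None
) -> SyntheticCorpusResult:
    """Generate a corpus, synonym table, and ground-truth manifest.

    Each planted triple appears in exactly F* distinct documents (chosen
    seeded-random without replacement); distractor triples are unique
    frequency-1 edges over a disjoint label namespace with polarity sampled
    from the configured mix; isolated mentions attach to random documents and
    must be pruned by graph construction.
    """
    schema = schema or SchemaConfig()
    rng = np.random.default_rng(spec.seed)
    synmap = SynonymMap(
        entries={
            canonical: {v for v, _ in variants}
            for canonical, variants in spec.variant_table.items()
        }
    )
    substituter = _VariantSubstituter(spec.variant_table, synmap.options)

    width = len(str(spec.n_documents))
    builders = [
        _DocBuilder(f"1{str(i + 1).zfill(max(width, 6))}")
        for i in range(spec.n_documents)
    ]

    def category_of(label: str, fallback: str = "nutrition") -> str:
        return spec.label_categories.get(label, fallback)

    def emit_instance(builder: _DocBuilder, edge: PlantedEdge) -> None:
        src_mid = builder.add_mention(
            category_of(edge.source), substituter.surface_for(edge.source)
        )
        tgt_mid = builder.add_mention(
            category_of(edge.target), substituter.surface_for(edge.target)
        )
        builder.add_relation(edge.relation_type, edge.polarity, src_mid, tgt_mid)

    triples: dict[tuple[str, str, str], dict] = {}
    pw_multiplier = {c: schema.multiplier(c) for c in POLARITY_CLASSES}

    # planted triples at their target frequencies
    for edge in spec.planted_edges:
        key = (edge.source, edge.target, edge.relation_type)
        if key in triples:
            raise ValueError(f"planted triple {key} listed twice")
        chosen = sorted(
            int(i) for i in rng.choice(spec.n_documents, size=edge.frequency, replace=False)
        )
        for doc_idx in chosen:
            emit_instance(builders[doc_idx], edge)
        for _ in range(edge.extra_instances):
            emit_instance(builders[chosen[0]], edge)
        doc_ids = [builders[i].doc.doc_id for i in chosen]
        triples[key] = {
            "frequency": edge.frequency,
            "polarity": edge.polarity,
            "instance_count": edge.frequency + edge.extra_instances,
            "weight": math.log(edge.frequency + 1) * pw_multiplier[edge.polarity],
            "docs": sorted(doc_ids),
        }

    # distractor edges: unique frequency-1 triples over a disjoint namespace
    types_by_class: dict[str, list[str]] = {c: [] for c in POLARITY_CLASSES}
    for rtype in schema.relation_types:
        types_by_class[schema.default_polarity(rtype)].append(rtype)
    classes = list(POLARITY_CLASSES)  # (beneficial, harmful, neutral)
    mix = {
        "neutral": spec.polarity_mix[0],
        "beneficial": spec.polarity_mix[1],
        "harmful": spec.polarity_mix[2],
    }
    probs = [mix[c] for c in classes]
    categories = list(schema.categories)
    for i in range(spec.n_distractor_edges):
        polarity = classes[int(rng.choice(len(classes), p=probs))]
        rtype = types_by_class[polarity][
            int(rng.integers(len(types_by_class[polarity])))
        ]
        cat_a = categories[int(rng.integers(len(categories)))]
        cat_b = categories[int(rng.integers(len(categories)))]
        src = f"{cat_a} item {i:04d}a"
        tgt = f"{cat_b} item {i:04d}b"
        doc_idx = int(rng.integers(spec.n_documents))
        builder = builders[doc_idx]
        src_mid = builder.add_mention(cat_a, src)
        tgt_mid = builder.add_mention(cat_b, tgt)
        builder.add_relation(rtype, polarity, src_mid, tgt_mid)
        triples[(src, tgt, rtype)] = {
            "frequency": 1,
            "polarity": polarity,
            "instance_count": 1,
            "weight": math.log(2) * pw_multiplier[polarity],
            "docs": [builder.doc.doc_id],
        }

    # isolated mentions: must be pruned by graph construction
    for i in range(spec.n_isolated_mentions):
        cat = categories[int(rng.integers(len(categories)))]
        doc_idx = int(rng.integers(spec.n_documents))
        builders[doc_idx].add_mention(cat, f"orphan item {i:03d}")

    corpus = Corpus(documents=[b.doc for b in builders])
    manifest = _build_manifest(spec, corpus, triples, substituter)
    return SyntheticCorpusResult(
        corpus=corpus,
        synonym_map=synmap,
        manifest=manifest,
        pathways=spec.pathways,
        marker_sets=spec.marker_sets,
        spec=spec,
    )


def _build_manifest(
    spec: SyntheticSpec,
    corpus: Corpus,
    triples: dict[tuple[str, str, str], dict],
    substituter: _VariantSubstituter,
) -> GroundTruthManifest:
    nodes = {n for key in triples for n in key[:2]}
    polarity_counts = {c: 0 for c in POLARITY_CLASSES}
    for value in triples.values():
        polarity_counts[value["polarity"]] += 1

    pathway_metrics: dict[str, dict] = {}
    for pathway in spec.pathways:
        keys = spec.pathway_triples.get(pathway.pathway_id, ())
        docs: set[str] = set()
        rels = 0
        for key in keys:
            docs |= set(triples[key]["docs"])
            rels += triples[key]["instance_count"]
        pathway_metrics[pathway.pathway_id] = {"docs": len(docs), "rels": rels}

    pair_set = {(s, t) for (s, t, _r) in triples}
    marker_coverage: dict[str, dict] = {}
    for ms in spec.marker_sets:
        detected = sum(
            1
            for m in ms.markers
            if any(term.casefold() in {n.casefold() for n in nodes} for term in m.terms)
        )
        found = sum(1 for pair in ms.expected_edges if pair in pair_set)
        marker_coverage[ms.pathway_id] = {
            "M_detected": detected,
            "M_total": len(ms.markers),
            "R_found": found if ms.expected_edges else None,
            "R_expected": len(ms.expected_edges) if ms.expected_edges else None,
        }

    return GroundTruthManifest(
        n_documents=spec.n_documents,
        mentions_total=corpus.n_mentions,
        relations_total=corpus.n_relations,
        mentions_unified=substituter.unified,
        normalized_forms=len(substituter.unified_forms),
        n_nodes=len(nodes),
        n_edges=len(triples),
        triples=triples,
        polarity_edge_counts=polarity_counts,
        pathway_metrics=pathway_metrics,
        marker_coverage=marker_coverage,
    )


def write_corpus(result: SyntheticCorpusResult, outdir: str | Path) -> dict[str, Path]:
    """Write the generated corpus in the formats the pipeline consumes."""
    outdir = Path(outdir)
    corpus_dir = outdir / "corpus"
    corpus_dir.mkdir(parents=True, exist_ok=True)
    markers_dir = outdir / "markers"
    markers_dir.mkdir(parents=True, exist_ok=True)
    schema = SchemaConfig()
    for doc in result.corpus:
        (corpus_dir / f"{doc.doc_id}.ann").write_text(
            write_standoff(doc, schema), encoding="utf-8"
        )
    write_synonym_table(result.synonym_map, outdir / "synonyms.tsv")
    (outdir / "pathways.json").write_text(
        json.dumps(
            {"pathways": [p.to_dict() for p in result.pathways]},
            indent=2,
            sort_keys=True,
        )
        + "\n",
        encoding="utf-8",
    )
    marker_paths = []
    for ms in result.marker_sets:
        path = markers_dir / f"{ms.pathway_id}.json"
        path.write_text(
            json.dumps(ms.to_dict(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        marker_paths.append(path)
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest.to_dict(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return {
        "corpus": corpus_dir,
        "synonyms": outdir / "synonyms.tsv",
        "pathways": outdir / "pathways.json",
        "markers": markers_dir,
        "manifest": outdir / "manifest.json",
    }


# ---------------------------------------------------------------------------
# default study conditions


def default_spec(seed: int = 42, **overrides) -> SyntheticSpec:
    """The packaged generation conditions (a scaled-down literature corpus).

    120 documents, 300 background edges at the literature polarity mix
    (62.6% neutral / 23.1% beneficial / 14.3% harmful), planted frequencies
    spanning 1-9, three lexical-variant groups, 15 isolated mentions, and
    two planted four-stage mechanistic chains with marker sets for coverage
    benchmarking.  The marker sets are synthetic stand-ins for curated
    KEGG/Reactome marker lists.
    """
    planted = (
        PlantedEdge("dietary fiber", "gut microbiota", "affects", "neutral", 9),
        PlantedEdge("probiotics", "gut microbiota", "associated_with", "neutral", 6),
        PlantedEdge("mediterranean diet", "gut microbiota", "benefits", "beneficial", 4),
        PlantedEdge(
            "gut microbiota", "short-chain fatty acids", "increases", "beneficial", 4
        ),
        PlantedEdge("red meat", "tmao", "harms", "harmful", 4),
        PlantedEdge(
            "polyphenols", "akkermansia muciniphila", "benefits", "beneficial", 3
        ),
        PlantedEdge("gut microbiota", "inflammation", "reduces", "harmful", 2),
        # beneficial fiber -> butyrate chain
        PlantedEdge(
            "whole grain fiber",
            "faecalibacterium prausnitzii",
            "increases",
            "beneficial",
            5,
            extra_instances=1,
        ),
        PlantedEdge(
            "faecalibacterium prausnitzii", "butyrate", "increases", "beneficial", 4
        ),
        PlantedEdge("butyrate", "gut inflammation", "reduces", "harmful", 3),
        # harmful endotoxemia chain (polarity overrides the type default)
        PlantedEdge("western diet", "gut dysbiosis", "causes", "harmful", 4),
        PlantedEdge("gut dysbiosis", "endotoxin lps", "increases", "harmful", 3),
        PlantedEdge("endotoxin lps", "insulin resistance", "increases", "harmful", 2),
    )
    label_categories = {
        "dietary fiber": "nutrition",
        "probiotics": "nutrition",
        "mediterranean diet": "nutrition",
        "red meat": "nutrition",
        "polyphenols": "nutrition",
        "whole grain fiber": "nutrition",
        "western diet": "nutrition",
        "gut microbiota": "microbiome",
        "akkermansia muciniphila": "microbiome",
        "faecalibacterium prausnitzii": "microbiome",
        "gut dysbiosis": "microbiome",
        "short-chain fatty acids": "metabolite",
        "tmao": "metabolite",
        "butyrate": "metabolite",
        "endotoxin lps": "metabolite",
        "inflammation": "physiological_process",
        "gut inflammation": "clinical_outcome",
        "insulin resistance": "disease",
    }
    variant_table = {
        "gut microbiota": (("intestinal flora", 3), ("gut microbiome", 4)),
        "short-chain fatty acids": (("SCFA", 2), ("SCFAs", 1)),
        "mediterranean diet": (("Mediterranean diet (MD)", 1), ("aMED", 1)),
    }
    pathways = (
        PathwayDefinition(
            pathway_id="fiber_butyrate_inflammation",
            name="Fiber-Faecalibacterium-Butyrate-Inflammation",
            polarity_claim="beneficial",
            stages=_stages(
                diet=("whole grain fiber",),
                microbiome=("faecalibacterium",),
                metabolite=("butyrate",),
                outcome=("gut inflammation",),
            ),
        ),
        PathwayDefinition(
            pathway_id="westerndiet_lps_insulin",
            name="Western diet-Dysbiosis-LPS-Insulin resistance",
            polarity_claim="harmful",
            stages=_stages(
                diet=("western diet",),
                microbiome=("gut dysbiosis",),
                metabolite=("endotoxin",),
                outcome=("insulin resistance",),
            ),
        ),
    )
    pathway_triples = {
        "fiber_butyrate_inflammation": (
            ("whole grain fiber", "faecalibacterium prausnitzii", "increases"),
            ("faecalibacterium prausnitzii", "butyrate", "increases"),
            ("butyrate", "gut inflammation", "reduces"),
        ),
        "westerndiet_lps_insulin": (
            ("western diet", "gut dysbiosis", "causes"),
            ("gut dysbiosis", "endotoxin lps", "increases"),
            ("endotoxin lps", "insulin resistance", "increases"),
        ),
    }
    marker_sets = (
        MarkerSet(
            pathway_id="butanoate_metabolism",
            external_ref="KEGG map00650 (synthetic stand-in)",
            markers=_markers(
                "whole grain fiber",
                "faecalibacterium prausnitzii",
                "butyrate",
                "gut inflammation",
                "crotonoyl-coa",
            ),
            expected_edges=(
                ("whole grain fiber", "faecalibacterium prausnitzii"),
                ("faecalibacterium prausnitzii", "butyrate"),
                ("butyrate", "gut inflammation"),
                ("whole grain fiber", "butyrate"),
            ),
        ),
        MarkerSet(
            pathway_id="endotoxemia_cascade",
            external_ref="Reactome R-HSA-168898 (synthetic stand-in)",
            markers=_markers(
                "western diet",
                "gut dysbiosis",
                "endotoxin lps",
                "insulin resistance",
                "tlr4",
                "nf-kb signaling",
            ),
            expected_edges=(
                ("western diet", "gut dysbiosis"),
                ("gut dysbiosis", "endotoxin lps"),
                ("endotoxin lps", "insulin resistance"),
                ("endotoxin lps", "tlr4"),
            ),
        ),
        MarkerSet(
            pathway_id="scfa_production",
            external_ref="KEGG map00650 (synthetic stand-in, SCFA arm)",
            markers=_markers(
                "gut microbiota",
                "short-chain fatty acids",
                "dietary fiber",
                "probiotics",
            ),
            expected_edges=(
                ("dietary fiber", "gut microbiota"),
                ("probiotics", "gut microbiota"),
                ("gut microbiota", "short-chain fatty acids"),
            ),
        ),
        MarkerSet(
            pathway_id="tmao_cascade",
            external_ref="Reactome R-HSA-8964043 (synthetic stand-in)",
            markers=_markers("red meat", "tmao", "trimethylamine"),
            expected_edges=(
                ("red meat", "tmao"),
                ("red meat", "trimethylamine"),
            ),
        ),
        MarkerSet(
            pathway_id="polyphenol_akkermansia",
            external_ref="KEGG map00380 (synthetic stand-in)",
            markers=_markers(
                "polyphenols",
                "akkermansia muciniphila",
                "mediterranean diet",
                "inflammation",
            ),
            expected_edges=(
                ("polyphenols", "akkermansia muciniphila"),
                ("mediterranean diet", "polyphenols"),
            ),
        ),
    )
    base = SyntheticSpec(
        planted_edges=planted,
        label_categories=label_categories,
        variant_table=variant_table,
        pathways=pathways,
        pathway_triples=pathway_triples,
        marker_sets=marker_sets,
        seed=seed,
    )
    return replace(base, **overrides) if overrides else base


def _stages(**role_keywords: tuple[str, ...]):
    from .pathway_evidence import Stage

    return tuple(Stage(role=role, keywords=kws) for role, kws in role_keywords.items())


def _markers(*labels: str):
    from .pathway_benchmark import Marker

    return tuple(Marker(label=label) for label in labels)


# ---------------------------------------------------------------------------
# regression fixture (12 documents, hand-computable)


def regression_fixture() -> SyntheticCorpusResult:
    """A fixed 12-document corpus whose expectations were counted by hand.

    Exercises: three variant groups, two isolated (prunable) entities, one
    beneficial chain, one harmful chain with polarity overrides, and one
    polarity-conflict triple.  The companion expectations are frozen in
    :data:`REGRESSION_EXPECTED`.
    """
    doc_ids = [f"9{str(i).zfill(6)}" for i in range(1, 13)]
    builders = {d: _DocBuilder(d) for d in doc_ids}
    d = doc_ids  # d[0] is document 1

    def rel(doc, src_cat, src, rtype, tgt_cat, tgt, polarity):
        b = builders[doc]
        s = b.add_mention(src_cat, src)
        t = b.add_mention(tgt_cat, tgt)
        b.add_relation(rtype, polarity, s, t)

    # beneficial chain: dietary fiber -> gut microbiota -> SCFAs -> inflammation
    rel(d[0], "nutrition", "dietary fiber", "increases", "microbiome", "gut microbiota", "beneficial")
    rel(d[1], "nutrition", "dietary fiber", "increases", "microbiome", "intestinal flora", "beneficial")
    rel(d[1], "microbiome", "intestinal flora", "increases", "metabolite", "SCFA", "beneficial")
    rel(d[2], "microbiome", "gut microbiome", "increases", "metabolite", "SCFAs", "beneficial")
    rel(d[3], "microbiome", "gut microbiota", "increases", "metabolite", "short-chain fatty acids", "beneficial")
    rel(d[4], "metabolite", "SCFA", "reduces", "physiological_process", "inflammation", "harmful")
    # harmful chain with polarity overrides on `increases`
    rel(d[5], "nutrition", "high-fat diet", "causes", "microbiome", "dysbiosis", "neutral")
    rel(d[6], "nutrition", "high-fat diet", "causes", "microbiome", "dysbiosis", "neutral")
    rel(d[6], "microbiome", "dysbiosis", "increases", "metabolite", "lipopolysaccharide", "harmful")
    rel(d[7], "metabolite", "lipopolysaccharide", "increases", "disease", "insulin resistance", "harmful")
    # polarity-conflict triple: harmful vs beneficial -> tie -> neutral
    rel(d[8], "nutrition", "red meat", "affects", "metabolite", "TMAO", "harmful")
    rel(d[9], "nutrition", "red meat", "affects", "metabolite", "TMAO", "beneficial")
    # variant-heavy beneficial edge
    rel(d[10], "nutrition", "Mediterranean", "benefits", "clinical_outcome", "cardiovascular health", "beneficial")
    rel(d[11], "nutrition", "MedDiet", "benefits", "clinical_outcome", "cardiovascular health", "beneficial")
    # isolated mentions -> pruned
    builders[d[0]].add_mention("nutrition", "vitamin d")
    builders[d[5]].add_mention("nutrition", "polyphenols")

    corpus = Corpus(documents=[builders[i].doc for i in doc_ids])
    synmap = SynonymMap(
        entries={
            "gut microbiota": {"intestinal flora", "gut microbiome"},
            "short-chain fatty acids": {"SCFA", "SCFAs"},
            "mediterranean diet": {"Mediterranean", "MedDiet"},
        }
    )
    pathways = (
        PathwayDefinition(
            pathway_id="fixture_beneficial",
            name="Fiber-Microbiota-SCFA-Inflammation",
            polarity_claim="beneficial",
            stages=_stages(
                diet=("dietary fiber",),
                microbiome=("gut microbiota",),
                metabolite=("short-chain fatty acids", "SCFA"),
                outcome=("inflammation",),
            ),
        ),
        PathwayDefinition(
            pathway_id="fixture_harmful",
            name="High-fat diet-Dysbiosis-LPS-Insulin resistance",
            polarity_claim="harmful",
            stages=_stages(
                diet=("high-fat diet",),
                microbiome=("dysbiosis",),
                metabolite=("lipopolysaccharide", "LPS"),
                outcome=("insulin resistance",),
            ),
        ),
    )
    triples = {
        key: dict(value)
        for key, value in REGRESSION_EXPECTED["triples"].items()
    }
    manifest = GroundTruthManifest(
        n_documents=12,
        mentions_total=REGRESSION_EXPECTED["mentions_total"],
        relations_total=REGRESSION_EXPECTED["relations_total"],
        mentions_unified=REGRESSION_EXPECTED["mentions_unified"],
        normalized_forms=REGRESSION_EXPECTED["normalized_forms"],
        n_nodes=REGRESSION_EXPECTED["n_nodes"],
        n_edges=REGRESSION_EXPECTED["n_edges"],
        triples=triples,
        polarity_edge_counts=dict(REGRESSION_EXPECTED["polarity_edge_counts"]),
        pathway_metrics=dict(REGRESSION_EXPECTED["pathway_metrics"]),
        marker_coverage={},
    )
    spec = SyntheticSpec(
        n_documents=12,
        n_distractor_edges=0,
        n_isolated_mentions=2,
        pathways=pathways,
        seed=0,
    )
    return SyntheticCorpusResult(
        corpus=corpus,
        synonym_map=synmap,
        manifest=manifest,
        pathways=pathways,
        marker_sets=(),
        spec=spec,
    )


_LN2 = math.log(2)
_LN3 = math.log(3)
_LN4 = math.log(4)

#: Hand-computed expectations for :func:`regression_fixture`.
REGRESSION_EXPECTED: dict = {
    "mentions_total": 30,  # 2 * 14 relation instances + 2 isolated
    "relations_total": 14,
    "mentions_unified": 8,  # intestinal flora x2, gut microbiome, SCFA x2,
    #                         SCFAs, Mediterranean, MedDiet
    "normalized_forms": 3,
    "n_nodes": 12,
    "n_edges": 8,
    "polarity_edge_counts": {"beneficial": 3, "harmful": 3, "neutral": 2},
    "pathway_metrics": {
        "fixture_beneficial": {"docs": 5, "rels": 6},
        "fixture_harmful": {"docs": 3, "rels": 4},
    },
    "triples": {
        ("dietary fiber", "gut microbiota", "increases"): {
            "frequency": 2, "polarity": "beneficial",
            "instance_count": 2, "weight": _LN3 * 1.2,
            "docs": ["9000001", "9000002"],
        },
        ("gut microbiota", "short-chain fatty acids", "increases"): {
            "frequency": 3, "polarity": "beneficial",
            "instance_count": 3, "weight": _LN4 * 1.2,
            "docs": ["9000002", "9000003", "9000004"],
        },
        ("short-chain fatty acids", "inflammation", "reduces"): {
            "frequency": 1, "polarity": "harmful",
            "instance_count": 1, "weight": _LN2 * 1.1,
            "docs": ["9000005"],
        },
        ("high-fat diet", "dysbiosis", "causes"): {
            "frequency": 2, "polarity": "neutral",
            "instance_count": 2, "weight": _LN3 * 1.0,
            "docs": ["9000006", "9000007"],
        },
        ("dysbiosis", "lipopolysaccharide", "increases"): {
            "frequency": 1, "polarity": "harmful",
            "instance_count": 1, "weight": _LN2 * 1.1,
            "docs": ["9000007"],
        },
        ("lipopolysaccharide", "insulin resistance", "increases"): {
            "frequency": 1, "polarity": "harmful",
            "instance_count": 1, "weight": _LN2 * 1.1,
            "docs": ["9000008"],
        },
        ("red meat", "tmao", "affects"): {
            "frequency": 2, "polarity": "neutral",  # 1-1 conflict -> neutral
            "instance_count": 2, "weight": _LN3 * 1.0,
            "docs": ["9000009", "9000010"],
        },
        ("mediterranean diet", "cardiovascular health", "benefits"): {
            "frequency": 2, "polarity": "beneficial",
            "instance_count": 2, "weight": _LN3 * 1.2,
            "docs": ["9000011", "9000012"],
        },
    },
}
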