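"""Aggregate relation instances into unique polarity-weighted edges.

Each unique (source label, target label, relation type) triple becomes one
directed edge.  Its evidence frequency F is the number of *distinct*
supporting abstracts, and its composite weight is

    W = ln(F + 1) * P

with the natural logarithm damping high-frequency associations and P a
polarity multiplier (1.2 beneficial, 1.1 harmful, 1.0 neutral).  Entities
participating in no relation are pruned, so the graph contains only
relationally connected concepts.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import pandas as pd

from ._util import pct, round_half_up
from .annotation_io import Corpus
from .consolidation import ConsolidationReport, SynonymMap, apply_consolidation
from .schema import POLARITY_CLASSES, SchemaConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PolarityWeights:
    """Polarity multipliers P of the edge-weighting function."""

    beneficial: float = 1.2
    harmful: float = 1.1
    neutral: float = 1.0

    def __post_init__(self) -> None:
        if min(self.beneficial, self.harmful, self.neutral) <= 0:
            raise ValueError("polarity multipliers must be strictly positive")

    def multiplier(self, polarity: str) -> float:
        return {
            "beneficial": self.beneficial,
            "harmful": self.harmful,
            "neutral": self.neutral,
        }[polarity]

    @classmethod
    def from_schema(cls, schema: SchemaConfig) -> "PolarityWeights":
        return cls(**schema.polarity_multipliers)


def compute_edge_weight(
    frequency: int, polarity: str, pw: PolarityWeights = PolarityWeights()
) -> float:
    """W = ln(F + 1) * P.  An edge cannot exist without evidence (F >= 1)."""
    if frequency < 1:
        raise ValueError("edge frequency must be >= 1")
    return math.log(frequency + 1) * pw.multiplier(polarity)


@dataclass(frozen=True)
class WeightedEdge:
    """One unique (source, target, relation type) triple with its evidence."""

    source: str
    target: str
    relation_type: str
    polarity: str
    frequency: int
    supporting_docs: frozenset[str]
    instance_count: int
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.frequency != len(self.supporting_docs) or self.frequency < 1:
            raise ValueError("frequency must equal |supporting_docs| >= 1")
        if self.instance_count < self.frequency:
            raise ValueError("instance_count cannot be below frequency")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.relation_type)


def _resolve_polarity(polarities: list[str]) -> tuple[str, bool]:
    """Majority polarity over merged instances; ties resolve to neutral."""
    counts = Counter(polarities)
    conflict = len(counts) > 1
    top = counts.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return "neutral", conflict
    return top[0][0], conflict


def aggregate_edges(
    corpus: Corpus, schema: SchemaConfig | None = None
) -> list[WeightedEdge]:
    """Merge relation instances into unique triples (weights left unset).

    Assumes consolidation has already been applied: grouping is by the
    mentions' (normalized) surface labels.  Self-loops arising after
    consolidation are dropped with a warning.
    """
    del schema  # vocabulary enforcement happens at parse time
    grouped: dict[tuple[str, str, str], dict] = defaultdict(
        lambda: {"docs": set(), "instances": 0, "polarities": []}
    )
    self_loops = 0
    for doc in corpus:
        index = doc.mention_index()
        for rel in doc.relations:
            src = index[rel.source_mention].surface.strip()
            tgt = index[rel.target_mention].surface.strip()
            if not src or not tgt:
                logger.warning(
                    "%s/%s: empty endpoint label, skipped", doc.doc_id, rel.relation_id
                )
                continue
            if src == tgt:
                self_loops += 1
                logger.warning(
                    "%s/%s: self-loop %r after consolidation, dropped",
                    doc.doc_id,
                    rel.relation_id,
                    src,
                )
                continue
            bucket = grouped[(src, tgt, rel.relation_type)]
            bucket["docs"].add(doc.doc_id)
            bucket["instances"] += 1
            bucket["polarities"].append(rel.polarity)

    edges: list[WeightedEdge] = []
    n_conflicts = 0
    for (src, tgt, rtype), bucket in sorted(grouped.items()):
        polarity, conflict = _resolve_polarity(bucket["polarities"])
        if conflict:
            n_conflicts += 1
            logger.info(
                "polarity conflict on (%s, %s, %s): %s -> %s",
                src,
                tgt,
                rtype,
                Counter(bucket["polarities"]),
                polarity,
            )
        edges.append(
            WeightedEdge(
                source=src,
                target=tgt,
                relation_type=rtype,
                polarity=polarity,
                frequency=len(bucket["docs"]),
                supporting_docs=frozenset(bucket["docs"]),
                instance_count=bucket["instances"],
            )
        )
    if self_loops:
        logger.info("dropped %d self-loop instance(s)", self_loops)
    return edges


def assign_weights(
    edges: list[WeightedEdge], pw: PolarityWeights = PolarityWeights()
) -> list[WeightedEdge]:
    return [
        replace(e, weight=compute_edge_weight(e.frequency, e.polarity, pw))
        for e in edges
    ]


@dataclass
class KnowledgeGraph:
    """The assembled evidence-weighted knowledge graph."""

    edges: list[WeightedEdge]
    node_categories: dict[str, str]
    node_mentions: dict[str, int]
    directed: bool = True
    build_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [e.key for e in self.edges]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (source, target, type) triples")
        endpoints = {n for e in self.edges for n in (e.source, e.target)}
        if endpoints - set(self.node_categories):
            raise ValueError("edge endpoint missing from node table")
        if set(self.node_categories) - endpoints:
            raise ValueError("graph contains a node with no incident edge")

    @property
    def nodes(self) -> list[str]:
        return sorted(self.node_categories)

    @property
    def n_nodes(self) -> int:
        return len(self.node_categories)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge(self, source: str, target: str, relation_type: str) -> WeightedEdge:
        for e in self.edges:
            if e.key == (source, target, relation_type):
                return e
        raise KeyError((source, target, relation_type))

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for label, category in self.node_categories.items():
            g.add_node(
                label, category=category, mentions=self.node_mentions.get(label, 0)
            )
        for e in self.edges:
            g.add_edge(
                e.source,
                e.target,
                key=e.relation_type,
                relation_type=e.relation_type,
                polarity=e.polarity,
                frequency=e.frequency,
                weight=e.weight if e.weight is not None else float("nan"),
                instance_count=e.instance_count,
                supporting_docs=";".join(sorted(e.supporting_docs)),
            )
        return g

    # -- tabular / file exports -------------------------------------------

    def edges_table(self) -> pd.DataFrame:
        rows = [
            {
                "source": e.source,
                "target": e.target,
                "relation_type": e.relation_type,
                "polarity": e.polarity,
                "frequency": e.frequency,
                "weight": e.weight,
                "instance_count": e.instance_count,
                "supporting_docs": ";".join(sorted(e.supporting_docs)),
            }
            for e in sorted(self.edges, key=lambda e: e.key)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "source",
                "target",
                "relation_type",
                "polarity",
                "frequency",
                "weight",
                "instance_count",
                "supporting_docs",
            ],
        )

    def nodes_table(self) -> pd.DataFrame:
        degree: Counter[str] = Counter()
        weighted: defaultdict[str, float] = defaultdict(float)
        for e in self.edges:
            w = e.weight or 0.0
            for end in (e.source, e.target):
                degree[end] += 1
                weighted[end] += w
        rows = [
            {
                "label": label,
                "category": self.node_categories[label],
                "mentions": self.node_mentions.get(label, 0),
                "degree": degree[label],
                "weighted_degree": weighted[label],
            }
            for label in self.nodes
        ]
        return pd.DataFrame(
            rows, columns=["label", "category", "mentions", "degree", "weighted_degree"]
        )

    def write_artifacts(self, outdir: str | Path) -> dict[str, Path]:
        """Write nodes/edges TSVs, GraphML, and the JSON build log."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "nodes": outdir / "nodes.tsv",
            "edges": outdir / "edges.tsv",
            "graphml": outdir / "graph.graphml",
            "log": outdir / "build_log.json",
        }
        self.nodes_table().to_csv(paths["nodes"], sep="\t", index=False)
        self.edges_table().to_csv(paths["edges"], sep="\t", index=False)
        nx.write_graphml(self.to_networkx(), paths["graphml"])
        paths["log"].write_text(
            json.dumps(self.build_log, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        return paths

    @classmethod
    def from_artifacts(cls, outdir: str | Path) -> "KnowledgeGraph":
        outdir = Path(outdir)
        nodes = pd.read_csv(outdir / "nodes.tsv", sep="\t")
        edges_df = pd.read_csv(outdir / "edges.tsv", sep="\t")
        edges = [
            WeightedEdge(
                source=row.source,
                target=row.target,
                relation_type=row.relation_type,
                polarity=row.polarity,
                frequency=int(row.frequency),
                supporting_docs=frozenset(str(row.supporting_docs).split(";")),
                instance_count=int(row.instance_count),
                weight=float(row.weight),
            )
            for row in edges_df.itertuples()
        ]
        log_path = outdir / "build_log.json"
        build_log = (
            json.loads(log_path.read_text(encoding="utf-8"))
            if log_path.exists()
            else {}
        )
        return cls(
            edges=edges,
            node_categories=dict(zip(nodes.label, nodes.category)),
            node_mentions=dict(zip(nodes.label, nodes.mentions)),
            build_log=build_log,
        )


def build_graph(
    corpus: Corpus,
    synonym_map: SynonymMap | None = None,
    schema: SchemaConfig | None = None,
    pw: PolarityWeights | None = None,
) -> KnowledgeGraph:
    """Full pipeline: consolidate -> aggregate -> weight -> prune.

    Pruning is implicit: nodes are created only from edge endpoints, so
    entities mentioned but never related are excluded.  The build log records
    counts at every stage.
    """
    schema = schema or SchemaConfig()
    synonym_map = synonym_map or SynonymMap.identity()
    pw = pw or PolarityWeights.from_schema(schema)

    consolidated, report = apply_consolidation(corpus, synonym_map)
    labels_before = {m.surface for d in consolidated for m in d.mentions}
    edges = assign_weights(aggregate_edges(consolidated, schema), pw)

    node_categories: dict[str, str] = {}
    node_mentions: Counter[str] = Counter()
    cat_votes: defaultdict[str, Counter] = defaultdict(Counter)
    for doc in consolidated:
        for m in doc.mentions:
            cat_votes[m.surface][m.category] += 1
            node_mentions[m.surface] += 1
    endpoints = {n for e in edges for n in (e.source, e.target)}
    for label in endpoints:
        votes = cat_votes.get(label, Counter())
        if votes:
            # majority category; ties broken alphabetically for determinism
            best = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
            node_categories[label] = min(
                (c for c, n in votes.items() if n == best[1])
            )
        else:
            node_categories[label] = "unknown"

    build_log = {
        "documents": len(corpus),
        "mentions": corpus.n_mentions,
        "relation_instances": corpus.n_relations,
        "mentions_unified": report.mentions_unified,
        "normalized_forms": report.normalized_forms,
        "entities_before_pruning": len(labels_before),
        "entities_after_pruning": len(endpoints),
        "unique_edges": len(edges),
    }
    logger.info("build complete: %s", build_log)
    return KnowledgeGraph(
        edges=edges,
        node_categories=node_categories,
        node_mentions={n: node_mentions[n] for n in endpoints},
        build_log=build_log,
    )


def consolidation_report_of(corpus: Corpus, synonym_map: SynonymMap) -> ConsolidationReport:
    return apply_consolidation(corpus, synonym_map)[1]


# ---------------------------------------------------------------------------
# polarity bookkeeping


def polarity_summary(graph: KnowledgeGraph) -> dict:
    """Per-class unique-edge counts and one-decimal percentage shares."""
    counts = Counter(e.polarity for e in graph.edges)
    total = graph.n_edges
    return {
        "counts": {c: counts.get(c, 0) for c in POLARITY_CLASSES},
        "shares": {
            c: (pct(counts.get(c, 0), total) if total else 0.0)
            for c in POLARITY_CLASSES
        },
        "total_edges": total,
    }


def polarity_shares_from_type_counts(
    type_counts: dict[str, int], schema: SchemaConfig | None = None
) -> dict:
    """Class shares from per-type unique-edge counts (type-default polarity)."""
    schema = schema or SchemaConfig()
    class_counts = {c: 0 for c in POLARITY_CLASSES}
    for rtype, n in type_counts.items():
        class_counts[schema.default_polarity(rtype)] += n
    total = sum(class_counts.values())
    return {
        "counts": class_counts,
        "shares": {c: pct(n, total) for c, n in class_counts.items()},
        "total_edges": total,
    }


def type_weight_summary(graph: KnowledgeGraph) -> pd.DataFrame:
    """Per-relation-type edge counts and mean weights (3 d.p.)."""
    rows = []
    by_type: defaultdict[str, list[float]] = defaultdict(list)
    for e in graph.edges:
        by_type[e.relation_type].append(e.weight or 0.0)
    for rtype in sorted(by_type):
        weights = by_type[rtype]
        rows.append(
            {
                "relation_type": rtype,
                "n_edges": len(weights),
                "mean_weight": round_half_up(sum(weights) / len(weights), 3),
            }
        )
    return pd.DataFrame(rows, columns=["relation_type", "n_edges", "mean_weight"])
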