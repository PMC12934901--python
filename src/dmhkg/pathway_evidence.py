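"""Internal validation: keyword-defined mechanistic pathways and their evidence.

A pathway is an ordered list of stages (diet -> microbiome -> metabolite ->
outcome), each with a curated keyword list.  A graph node matches a stage if
its normalized label equals a keyword case-insensitively or contains it as a
whole-word substring ("butyrate" matches "butyrate production" but not
"butyrogenesis").  An edge supports the pathway when both endpoints match
some stage and its direction is consistent with the stage order (source
stage index <= target stage index; same-stage links allowed).  Evidence is
quantified as the number of unique supporting documents and the number of
relation instances over all matched edges.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import pandas as pd

from .graph_builder import KnowledgeGraph, WeightedEdge

STAGE_ROLES = ("diet", "microbiome", "metabolite", "outcome")

#: Relation types rendered as an up/down arrow on the target in chain text.
_ARROW_UP = {"increases", "benefits"}
_ARROW_DOWN = {"reduces", "inhibits", "harms"}


@dataclass(frozen=True)
class Stage:
    role: str
    keywords: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError(f"stage {self.role!r} has an empty keyword list")


@dataclass(frozen=True)
class PathwayDefinition:
    pathway_id: str
    name: str
    polarity_claim: str
    stages: tuple[Stage, ...]
    expected_edges: tuple[tuple[str, str, str], ...] = ()

    def __post_init__(self) -> None:
        if len(self.stages) < 2:
            raise ValueError("a pathway needs at least 2 stages")

    @classmethod
    def from_dict(cls, data: dict) -> "PathwayDefinition":
        stages = tuple(
            Stage(role=s["role"], keywords=tuple(s["keywords"]))
            for s in data["stages"]
        )
        expected = tuple(
            (e[0], e[1], e[2] if len(e) > 2 else "*")
            for e in data.get("expected_edges", [])
        )
        return cls(
            pathway_id=data["pathway_id"],
            name=data.get("name", data["pathway_id"]),
            polarity_claim=data.get("polarity_claim", "beneficial"),
            stages=stages,
            expected_edges=expected,
        )

    def to_dict(self) -> dict:
        return {
            "pathway_id": self.pathway_id,
            "name": self.name,
            "polarity_claim": self.polarity_claim,
            "stages": [
                {"role": s.role, "keywords": list(s.keywords)} for s in self.stages
            ],
            "expected_edges": [list(e) for e in self.expected_edges],
        }


def load_pathway_definitions(path: str | Path) -> list[PathwayDefinition]:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if isinstance(data, dict):
        data = data.get("pathways", [data])
    return [PathwayDefinition.from_dict(d) for d in data]


# ---------------------------------------------------------------------------
# keyword matching


@lru_cache(maxsize=4096)
def _keyword_pattern(keyword: str) -> re.Pattern:
    return re.compile(
        r"(?<!\w)" + re.escape(keyword.strip()) + r"(?!\w)", re.IGNORECASE
    )


def keyword_matches(label: str, keyword: str) -> bool:
    """Case-insensitive equality or whole-word substring match."""
    if label.casefold() == keyword.strip().casefold():
        return True
    return _keyword_pattern(keyword) .search(label) is not None


def match_entities(graph: KnowledgeGraph, keywords: tuple[str, ...] | list[str]) -> set[str]:
    """Graph nodes matching any of the keywords."""
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    return {
        node
        for node in graph.nodes
        if any(keyword_matches(node, kw) for kw in keywords)
    }


def _stage_sets(graph: KnowledgeGraph, definition: PathwayDefinition) -> dict[str, set[int]]:
    """For each node, the set of stage indices whose keywords it matches."""
    stages: dict[str, set[int]] = {}
    for idx, stage in enumerate(definition.stages):
        for node in match_entities(graph, stage.keywords):
            stages.setdefault(node, set()).add(idx)
    return stages


# ---------------------------------------------------------------------------
# evidence metrics


@dataclass
class EvidenceMetrics:
    pathway_id: str
    docs: int
    rels: int
    matched_nodes: dict[str, list[str]]
    matched_edges: list[WeightedEdge] = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "pathway_id": self.pathway_id,
            "docs": self.docs,
            "rels": self.rels,
            "matched_nodes": self.matched_nodes,
            "matched_edges": [list(e.key) for e in self.matched_edges],
            "rels_semantics": "relation instances (not unique edges)",
        }


def pathway_evidence(
    graph: KnowledgeGraph, definition: PathwayDefinition
) -> EvidenceMetrics:
    """Unique-document and relation-instance support for a pathway.

    docs = |union of supporting documents over matched edges|;
    rels = sum of instance counts over matched edges.  A definition whose
    keywords match nothing yields all-zero metrics.
    """
    node_stages = _stage_sets(graph, definition)
    matched_edges: list[WeightedEdge] = []
    docs: set[str] = set()
    rels = 0
    for e in graph.edges:
        src_stages = node_stages.get(e.source)
        tgt_stages = node_stages.get(e.target)
        if not src_stages or not tgt_stages:
            continue
        # direction consistent with stage order: some assignment with
        # source stage <= target stage
        if min(src_stages) > max(tgt_stages):
            continue
        matched_edges.append(e)
        docs |= e.supporting_docs
        rels += e.instance_count
    matched_nodes = {
        stage.role: sorted(
            n for n, idxs in node_stages.items() if i in idxs
        )
        for i, stage in enumerate(definition.stages)
    }
    return EvidenceMetrics(
        pathway_id=definition.pathway_id,
        docs=len(docs),
        rels=rels,
        matched_nodes=matched_nodes,
        matched_edges=matched_edges,
    )


# ---------------------------------------------------------------------------
# chain extraction


@dataclass
class Chain:
    nodes: list[str]
    stage_indices: list[int]
    edges: list[list[WeightedEdge]]  # per hop, all parallel edges
    supporting_docs: set[str]

    def render(self) -> str:
        """Arrow rendering: polarity/type decides the mark on each target."""
        parts = [self.nodes[0]]
        for hop_edges, node in zip(self.edges, self.nodes[1:]):
            types = {e.relation_type for e in hop_edges}
            if types & _ARROW_DOWN:
                mark = " ↓"
            elif types & _ARROW_UP:
                mark = " ↑"
            else:
                mark = ""
            parts.append(f"{node}{mark}")
        return " → ".join(parts)


def extract_chains(
    graph: KnowledgeGraph, definition: PathwayDefinition, max_path_len: int = 6
) -> list[Chain]:
    """Enumerate simple directed paths visiting stages in non-decreasing order.

    Paths start at a first-stage (diet) match and end at a last-stage
    (outcome) match; stages may be skipped.  ``max_path_len`` caps the number
    of nodes per chain.
    """
    if max_path_len < 2:
        raise ValueError("max_path_len must be >= 2")
    node_stages = _stage_sets(graph, definition)
    last = len(definition.stages) - 1
    adjacency: dict[str, dict[str, list[WeightedEdge]]] = {}
    for e in graph.edges:
        adjacency.setdefault(e.source, {}).setdefault(e.target, []).append(e)

    chains: list[Chain] = []

    def dfs(node: str, stage: int, path: list[str], stages: list[int]) -> None:
        if last in node_stages.get(node, set()) and len(path) >= 2:
            hop_edges = [
                adjacency[u][v] for u, v in zip(path, path[1:])
            ]
            docs = {d for hop in hop_edges for e in hop for d in e.supporting_docs}
            chains.append(
                Chain(
                    nodes=list(path),
                    stage_indices=list(stages),
                    edges=hop_edges,
                    supporting_docs=docs,
                )
            )
        if len(path) >= max_path_len:
            return
        for nxt in sorted(adjacency.get(node, {})):
            if nxt in path:
                continue
            nxt_stages = {s for s in node_stages.get(nxt, set()) if s >= stage}
            if not nxt_stages:
                continue
            dfs(nxt, min(nxt_stages), path + [nxt], stages + [min(nxt_stages)])

    for start in sorted(node_stages):
        if 0 in node_stages[start]:
            dfs(start, 0, [start], [0])
    return chains


def evidence_table(
    graph: KnowledgeGraph,
    definitions: list[PathwayDefinition],
    max_path_len: int = 6,
) -> pd.DataFrame:
    """Table-style summary: pathway, polarity, docs, rels, best chain rendering."""
    rows = []
    for d in definitions:
        metrics = pathway_evidence(graph, d)
        chains = extract_chains(graph, d, max_path_len)
        best = max(
            chains,
            key=lambda c: (len(set(c.stage_indices)), len(c.nodes)),
            default=None,
        )
        rows.append(
            {
                "pathway": d.name,
                "polarity": d.polarity_claim,
                "docs": metrics.docs,
                "rels": metrics.rels,
                "n_chains": len(chains),
                "chain": best.render() if best else "",
            }
        )
    return pd.DataFrame(
        rows, columns=["pathway", "polarity", "docs", "rels", "n_chains", "chain"]
    )


def write_evidence_report(
    graph: KnowledgeGraph,
    definitions: list[PathwayDefinition],
    outdir: str | Path,
    max_path_len: int = 6,
    extra_metadata: dict | None = None,
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": outdir / "pathway_evidence.tsv",
        "json": outdir / "pathway_evidence.json",
    }
    evidence_table(graph, definitions, max_path_len).to_csv(
        paths["table"], sep="\t", index=False
    )
    payload = {
        "pathways": [pathway_evidence(graph, d).to_dict() for d in definitions],
    }
    if extra_metadata:
        payload.update(extra_metadata)
    paths["json"].write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths
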