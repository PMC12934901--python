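"""External validation: coverage of curated pathway marker sets.

For each reference pathway (e.g. a KEGG or Reactome map) a marker set lists
the expected entities, optionally with per-marker synonym lists, and
optionally the expected directed relationships among them.  Entity coverage
is the percentage of markers present as graph nodes,

    C_entity = M_detected / M_total * 100,

and edge coverage the percentage of expected connections present as edges
(any relation type),

    C_edge = R_found / R_expected * 100.

Marker matching reuses the whole-word, case-insensitive keyword rule; marker
synonym lists bridge database nomenclature ("butanoate") to literature
surface forms ("butyrate").  Percentages are reported to one decimal,
round-half-up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._util import pct, round_half_up
from .graph_builder import KnowledgeGraph
from .pathway_evidence import keyword_matches


@dataclass(frozen=True)
class Marker:
    label: str
    synonyms: tuple[str, ...] = ()

    @property
    def terms(self) -> tuple[str, ...]:
        return (self.label, *self.synonyms)


@dataclass(frozen=True)
class MarkerSet:
    pathway_id: str
    external_ref: str
    markers: tuple[Marker, ...]
    expected_edges: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("marker set must be non-empty")
        labels = {m.label for m in self.markers}
        for src, tgt in self.expected_edges:
            if src not in labels or tgt not in labels:
                raise ValueError(
                    f"expected edge ({src!r}, {tgt!r}) references a non-marker"
                )

    @classmethod
    def from_dict(cls, data: dict) -> "MarkerSet":
        markers = tuple(
            Marker(label=m, synonyms=())
            if isinstance(m, str)
            else Marker(label=m["label"], synonyms=tuple(m.get("synonyms", [])))
            for m in data["markers"]
        )
        return cls(
            pathway_id=data["pathway_id"],
            external_ref=data.get("external_ref", ""),
            markers=markers,
            expected_edges=tuple(
                (e[0], e[1]) for e in data.get("expected_edges", [])
            ),
        )

    def to_dict(self) -> dict:
        return {
            "pathway_id": self.pathway_id,
            "external_ref": self.external_ref,
            "markers": [
                {"label": m.label, "synonyms": list(m.synonyms)} for m in self.markers
            ],
            "expected_edges": [list(e) for e in self.expected_edges],
        }


def load_marker_set(path: str | Path) -> MarkerSet:
    return MarkerSet.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass
class CoverageReport:
    pathway_id: str
    external_ref: str
    m_detected: int
    m_total: int
    detected_markers: list[str] = field(default_factory=list)
    missing_markers: list[str] = field(default_factory=list)
    r_found: int | None = None
    r_expected: int | None = None
    found_edges: list[tuple[str, str]] = field(default_factory=list)
    missing_edges: list[tuple[str, str]] = field(default_factory=list)

    @property
    def c_entity(self) -> float:
        return pct(self.m_detected, self.m_total)

    @property
    def c_edge(self) -> float | None:
        if self.r_expected is None or self.r_expected == 0:
            return None
        return pct(self.r_found or 0, self.r_expected)

    def to_dict(self) -> dict:
        return {
            "pathway_id": self.pathway_id,
            "external_ref": self.external_ref,
            "M_detected": self.m_detected,
            "M_total": self.m_total,
            "C_entity": self.c_entity,
            "detected_markers": self.detected_markers,
            "missing_markers": self.missing_markers,
            "R_found": self.r_found,
            "R_expected": self.r_expected,
            "C_edge": self.c_edge,
            "found_edges": [list(e) for e in self.found_edges],
            "missing_edges": [list(e) for e in self.missing_edges],
        }


def _marker_nodes(graph: KnowledgeGraph, marker: Marker) -> set[str]:
    return {
        node
        for node in graph.nodes
        if any(keyword_matches(node, term) for term in marker.terms)
    }


def entity_coverage(graph: KnowledgeGraph, marker_set: MarkerSet) -> CoverageReport:
    """Entity part: a marker is detected if any node matches it or a synonym."""
    detected, missing = [], []
    for marker in marker_set.markers:
        (detected if _marker_nodes(graph, marker) else missing).append(marker.label)
    return CoverageReport(
        pathway_id=marker_set.pathway_id,
        external_ref=marker_set.external_ref,
        m_detected=len(detected),
        m_total=len(marker_set.markers),
        detected_markers=detected,
        missing_markers=missing,
    )


def edge_coverage(
    graph: KnowledgeGraph, marker_set: MarkerSet, undirected: bool = False
) -> CoverageReport:
    """Edge part: an expected (src, tgt) pair is found when any edge (any
    relation type) links a src-marker node to a tgt-marker node in the stated
    direction (both directions with ``undirected``).  Entity coverage is
    included; the edge part is not-applicable when no expected edges exist.
    """
    report = entity_coverage(graph, marker_set)
    if not marker_set.expected_edges:
        return report
    by_label = {m.label: m for m in marker_set.markers}
    edge_pairs = {(e.source, e.target) for e in graph.edges}
    found, missing = [], []
    for src_label, tgt_label in marker_set.expected_edges:
        src_nodes = _marker_nodes(graph, by_label[src_label])
        tgt_nodes = _marker_nodes(graph, by_label[tgt_label])
        hit = any(
            (s, t) in edge_pairs or (undirected and (t, s) in edge_pairs)
            for s in src_nodes
            for t in tgt_nodes
        )
        (found if hit else missing).append((src_label, tgt_label))
    report.r_found = len(found)
    report.r_expected = len(marker_set.expected_edges)
    report.found_edges = found
    report.missing_edges = missing
    return report


def benchmark_summary(reports: list[CoverageReport]) -> tuple[pd.DataFrame, float]:
    """Benchmark table plus the unweighted mean entity coverage (1 d.p.)."""
    if not reports:
        raise ValueError("need at least one coverage report")
    rows = []
    for r in reports:
        rows.append(
            {
                "pathway": r.pathway_id,
                "external_ref": r.external_ref,
                "entity_coverage": f"{r.c_entity}% ({r.m_detected}/{r.m_total})",
                "edge_coverage": (
                    f"{r.c_edge}% ({r.r_found}/{r.r_expected})"
                    if r.c_edge is not None
                    else "n/a"
                ),
            }
        )
    mean = round_half_up(sum(r.c_entity for r in reports) / len(reports), 1)
    return (
        pd.DataFrame(
            rows, columns=["pathway", "external_ref", "entity_coverage", "edge_coverage"]
        ),
        mean,
    )


def write_benchmark_report(
    reports: list[CoverageReport],
    outdir: str | Path,
    extra_metadata: dict | None = None,
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, mean = benchmark_summary(reports)
    paths = {"table": outdir / "benchmark.tsv", "json": outdir / "benchmark.json"}
    with paths["table"].open("w", encoding="utf-8") as fh:
        table.to_csv(fh, sep="\t", index=False)
        fh.write(f"# unweighted mean entity coverage\t{mean}\n")
    payload = {
        "mean_entity_coverage": mean,
        "pathways": [r.to_dict() for r in reports],
    }
    if extra_metadata:
        payload.update(extra_metadata)
    paths["json"].write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths
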