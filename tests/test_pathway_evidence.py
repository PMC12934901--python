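"""Keyword matching, pathway evidence metrics, and chain extraction."""

import math

import pytest

from dmhkg.graph_builder import KnowledgeGraph, WeightedEdge
from dmhkg.pathway_evidence import (
    PathwayDefinition,
    Stage,
    extract_chains,
    keyword_matches,
    match_entities,
    pathway_evidence,
)


def _kg(edge_specs):
    """edge_specs: (src, tgt, rtype, docs, instance_count)."""
    edges = [
        WeightedEdge(
            source=s,
            target=t,
            relation_type=r,
            polarity="neutral",
            frequency=len(docs),
            supporting_docs=frozenset(docs),
            instance_count=n,
            weight=math.log(len(docs) + 1),
        )
        for s, t, r, docs, n in edge_specs
    ]
    nodes = {n for e in edges for n in (e.source, e.target)}
    return KnowledgeGraph(
        edges=edges,
        node_categories={n: "nutrition" for n in nodes},
        node_mentions={n: 1 for n in nodes},
    )


def _definition(**stage_keywords):
    return PathwayDefinition(
        pathway_id="p",
        name="p",
        polarity_claim="beneficial",
        stages=tuple(
            Stage(role=r, keywords=tuple(kws)) for r, kws in stage_keywords.items()
        ),
    )


@pytest.mark.parametrize(
    ("label", "keyword", "expected"),
    [
        ("butyrate", "butyrate", True),
        ("butyrate production", "butyrate", True),
        ("butyrogenesis", "butyrate", False),
        ("Faecalibacterium prausnitzii", "Faecalibacterium", True),
        ("heart disease", "art", False),
        ("Butyrate", "butyrate", True),  # case-insensitive
    ],
)
def test_whole_word_keyword_matching(label, keyword, expected):
    assert keyword_matches(label, keyword) is expected


def test_match_entities(fixture_graph):
    matched = match_entities(fixture_graph, ["gut microbiota", "dysbiosis"])
    assert matched == {"gut microbiota", "dysbiosis"}
    assert match_entities(fixture_graph, ["no such entity"]) == set()
    with pytest.raises(ValueError):
        match_entities(fixture_graph, [])


def test_pathway_evidence_hand_count():
    # 3 chain edges supported by docs {d1,d2},{d2},{d3}, instances 2,1,1
    kg = _kg(
        [
            ("fiber", "microbe", "increases", {"d1", "d2"}, 2),
            ("microbe", "scfa", "increases", {"d2"}, 1),
            ("scfa", "health", "benefits", {"d3"}, 1),
            ("unrelated a", "unrelated b", "affects", {"d9"}, 1),
        ]
    )
    definition = _definition(
        diet=["fiber"], microbiome=["microbe"], metabolite=["scfa"], outcome=["health"]
    )
    metrics = pathway_evidence(kg, definition)
    assert metrics.docs == 3
    assert metrics.rels == 4
    assert len(metrics.matched_edges) == 3


def test_edge_against_stage_order_excluded():
    kg = _kg(
        [
            ("fiber", "health", "benefits", {"d1"}, 1),
            ("health", "fiber", "affects", {"d2"}, 1),  # outcome -> diet
        ]
    )
    definition = _definition(diet=["fiber"], outcome=["health"])
    metrics = pathway_evidence(kg, definition)
    assert [e.key for e in metrics.matched_edges] == [
        ("fiber", "health", "benefits")
    ]
    assert metrics.docs == 1 and metrics.rels == 1


def test_no_keyword_hits_gives_zero_metrics():
    kg = _kg([("a", "b", "affects", {"d1"}, 1)])
    metrics = pathway_evidence(kg, _definition(diet=["x"], outcome=["y"]))
    assert metrics.docs == 0 and metrics.rels == 0


def test_adding_keyword_never_decreases_evidence(fixture_graph):
    base = _definition(
        diet=["dietary fiber"],
        microbiome=["gut microbiota"],
        metabolite=["short-chain fatty acids"],
        outcome=["inflammation"],
    )
    wider = _definition(
        diet=["dietary fiber", "high-fat diet"],
        microbiome=["gut microbiota", "dysbiosis"],
        metabolite=["short-chain fatty acids", "lipopolysaccharide"],
        outcome=["inflammation", "insulin resistance"],
    )
    m0 = pathway_evidence(fixture_graph, base)
    m1 = pathway_evidence(fixture_graph, wider)
    assert m1.docs >= m0.docs and m1.rels >= m0.rels


def test_fixture_pathway_metrics_match_hand_counts(fixture_result, fixture_graph):
    for definition in fixture_result.pathways:
        truth = fixture_result.manifest.pathway_metrics[definition.pathway_id]
        metrics = pathway_evidence(fixture_graph, definition)
        assert (metrics.docs, metrics.rels) == (truth["docs"], truth["rels"])
        assert metrics.docs <= len(fixture_result.corpus)
        assert metrics.rels <= fixture_result.corpus.n_relations


def test_extract_chain_four_stage():
    kg = _kg(
        [
            ("fiber", "F. prausnitzii", "increases", {"d1"}, 1),
            ("F. prausnitzii", "butyrate", "increases", {"d2"}, 1),
            ("butyrate", "inflammation", "reduces", {"d3"}, 1),
        ]
    )
    definition = _definition(
        diet=["fiber"],
        microbiome=["prausnitzii"],
        metabolite=["butyrate"],
        outcome=["inflammation"],
    )
    chains = extract_chains(kg, definition)
    assert len(chains) == 1
    assert chains[0].nodes == ["fiber", "F. prausnitzii", "butyrate", "inflammation"]
    assert chains[0].supporting_docs == {"d1", "d2", "d3"}
    assert "inflammation ↓" in chains[0].render()


def test_stage_skip_allowed():
    kg = _kg([("fiber", "health", "benefits", {"d1"}, 1)])
    definition = _definition(
        diet=["fiber"], microbiome=["microbe"], outcome=["health"]
    )
    chains = extract_chains(kg, definition)
    assert len(chains) == 1 and chains[0].stage_indices == [0, 2]


def test_no_diet_stage_match_no_chains(fixture_graph):
    definition = _definition(diet=["nonexistent"], outcome=["inflammation"])
    assert extract_chains(fixture_graph, definition) == []


def test_max_path_len_validation(fixture_graph, fixture_result):
    with pytest.raises(ValueError):
        extract_chains(fixture_graph, fixture_result.pathways[0], max_path_len=1)


def test_planted_chains_recovered_without_spurious(default_result, default_graph):
    for definition in default_result.pathways:
        chains = extract_chains(default_graph, definition)
        assert len(chains) == 1
        assert len(chains[0].nodes) == 4
        # every chain edge also appears in the evidence metrics
        metrics = pathway_evidence(default_graph, definition)
        matched = {e.key for e in metrics.matched_edges}
        for hop in chains[0].edges:
            for e in hop:
                assert e.key in matched
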