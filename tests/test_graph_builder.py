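"""Edge aggregation, Eq.-style weighting, pruning, polarity bookkeeping."""

import math
from collections import defaultdict

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmhkg.annotation_io import AnnotatedDocument, Corpus, EntityMention, RelationInstance
from dmhkg.graph_builder import (
    PolarityWeights,
    aggregate_edges,
    build_graph,
    compute_edge_weight,
    polarity_shares_from_type_counts,
    polarity_summary,
)
from dmhkg.schema import RELATION_TYPES

#: Printed high-weight edges reproduced by ln(F+1) x P.
PRINTED_WEIGHTS = [
    (9, "neutral", 2, 2.30),
    (6, "neutral", 2, 1.95),
    (4, "beneficial", 2, 1.93),
    (5, "neutral", 2, 1.79),
    (4, "harmful", 2, 1.77),
    (3, "beneficial", 2, 1.66),
    (4, "neutral", 2, 1.61),
    (3, "neutral", 2, 1.39),
    (1, "neutral", 3, 0.693),
]

#: Published per-type unique-edge counts of the full-corpus graph.
PUBLISHED_TYPE_COUNTS = {
    "associated_with": 1588,
    "affects": 742,
    "causes": 361,
    "regulates": 153,
    "modifies": 74,
    "maintains": 57,
    "assists": 13,
    "benefits": 720,
    "increases": 381,
    "reduces": 402,
    "inhibits": 164,
    "harms": 117,
}


def _relation_corpus(instances):
    """instances: list of (doc_id, src_label, tgt_label, rtype, polarity)."""
    docs = {}
    for doc_id, src, tgt, rtype, polarity in instances:
        doc = docs.setdefault(doc_id, AnnotatedDocument(doc_id=doc_id))
        base = len(doc.mentions)
        doc.mentions.append(
            EntityMention(doc_id, f"T{base + 1}", "nutrition", src, 0, max(len(src), 1))
        )
        doc.mentions.append(
            EntityMention(doc_id, f"T{base + 2}", "metabolite", tgt, 0, max(len(tgt), 1))
        )
        doc.relations.append(
            RelationInstance(
                doc_id,
                f"R{len(doc.relations) + 1}",
                rtype,
                polarity,
                f"T{base + 1}",
                f"T{base + 2}",
            )
        )
    return Corpus(documents=list(docs.values()))


@pytest.mark.parametrize(("freq", "polarity", "ndigits", "expected"), PRINTED_WEIGHTS)
def test_weight_reproduces_printed_values(freq, polarity, ndigits, expected):
    w = compute_edge_weight(freq, polarity)
    assert round(w, ndigits) == pytest.approx(expected)


def test_weight_requires_evidence():
    with pytest.raises(ValueError):
        compute_edge_weight(0, "neutral")


@given(freq=st.integers(1, 500))
@settings(max_examples=50, derandomize=True)
def test_weight_monotone_and_polarity_ratios(freq):
    pw = PolarityWeights()
    w_n = compute_edge_weight(freq, "neutral", pw)
    assert compute_edge_weight(freq + 1, "neutral", pw) > w_n
    assert compute_edge_weight(freq, "beneficial", pw) / w_n == pytest.approx(1.2)
    assert compute_edge_weight(freq, "harmful", pw) / w_n == pytest.approx(1.1)


def test_aggregate_unique_docs_vs_instances():
    # two docs each annotating the triple once, one doc annotating it twice
    corpus = _relation_corpus(
        [
            ("d1", "fiber", "butyrate", "increases", "beneficial"),
            ("d2", "fiber", "butyrate", "increases", "beneficial"),
            ("d2", "fiber", "butyrate", "increases", "beneficial"),
        ]
    )
    edges = aggregate_edges(corpus)
    assert len(edges) == 1
    assert edges[0].frequency == 2
    assert edges[0].instance_count == 3
    assert edges[0].supporting_docs == frozenset({"d1", "d2"})


def test_relation_type_is_part_of_edge_key():
    corpus = _relation_corpus(
        [
            ("d1", "fiber", "butyrate", "increases", "beneficial"),
            ("d1", "fiber", "butyrate", "affects", "neutral"),
        ]
    )
    assert len(aggregate_edges(corpus)) == 2


def test_empty_corpus_empty_edges():
    assert aggregate_edges(Corpus()) == []


def test_polarity_conflict_majority_then_neutral_tie():
    majority = _relation_corpus(
        [
            ("d1", "a", "b", "affects", "harmful"),
            ("d2", "a", "b", "affects", "harmful"),
            ("d3", "a", "b", "affects", "beneficial"),
        ]
    )
    assert aggregate_edges(majority)[0].polarity == "harmful"
    tie = _relation_corpus(
        [
            ("d1", "a", "b", "affects", "harmful"),
            ("d2", "a", "b", "affects", "beneficial"),
        ]
    )
    assert aggregate_edges(tie)[0].polarity == "neutral"


def test_self_loops_dropped():
    corpus = _relation_corpus([("d1", "x", "x", "affects", "neutral")])
    assert aggregate_edges(corpus) == []


def test_isolated_entities_pruned(schema):
    corpus = _relation_corpus([("d1", "fiber", "butyrate", "increases", "beneficial")])
    corpus.documents[0].mentions.append(
        EntityMention("d1", "T99", "nutrition", "unrelated label", 0, 5)
    )
    kg = build_graph(corpus)
    assert kg.n_nodes == 2
    assert kg.build_log["entities_before_pruning"] == 3
    assert kg.build_log["entities_after_pruning"] == 2


def test_single_relation_graph():
    kg = build_graph(
        _relation_corpus([("d1", "fiber", "butyrate", "increases", "beneficial")])
    )
    assert kg.n_nodes == 2 and kg.n_edges == 1
    assert kg.edges[0].weight == pytest.approx(math.log(2) * 1.2)


@given(
    data=st.lists(
        st.tuples(
            st.sampled_from(["d1", "d2", "d3", "d4"]),
            st.sampled_from(["a", "b", "c"]),
            st.sampled_from(["x", "y", "z"]),
            st.sampled_from(RELATION_TYPES[:4]),
            st.sampled_from(["beneficial", "harmful", "neutral"]),
        ),
        min_size=1,
        max_size=25,
    )
)
@settings(max_examples=60, derandomize=True)
def test_aggregation_matches_bruteforce_oracle(data):
    corpus = _relation_corpus(data)
    edges = {e.key: e for e in aggregate_edges(corpus)}
    # independent brute-force grouping over all triples
    expected = defaultdict(lambda: {"docs": set(), "n": 0})
    for doc_id, src, tgt, rtype, _pol in data:
        bucket = expected[(src, tgt, rtype)]
        bucket["docs"].add(doc_id)
        bucket["n"] += 1
    assert set(edges) == set(expected)
    for key, bucket in expected.items():
        assert edges[key].frequency == len(bucket["docs"])
        assert edges[key].instance_count == bucket["n"]
    # evidence conservation
    assert sum(e.instance_count for e in edges.values()) == len(data)
    assert sum(e.frequency for e in edges.values()) <= len(data)


def test_manifest_frequency_and_weight_recovery(default_result, default_graph):
    manifest = default_result.manifest
    assert default_graph.n_nodes == manifest.n_nodes
    assert default_graph.n_edges == manifest.n_edges
    for edge in default_graph.edges:
        truth = manifest.triples[edge.key]
        assert edge.frequency == truth["frequency"]
        assert edge.instance_count == truth["instance_count"]
        assert edge.polarity == truth["polarity"]
        assert edge.weight == pytest.approx(truth["weight"], abs=1e-9)
        assert sorted(edge.supporting_docs) == truth["docs"]


def test_polarity_summary_counts(fixture_graph, fixture_result):
    summary = polarity_summary(fixture_graph)
    assert summary["counts"] == fixture_result.manifest.polarity_edge_counts
    assert summary["total_edges"] == 8


def test_published_type_counts_give_published_shares():
    summary = polarity_shares_from_type_counts(PUBLISHED_TYPE_COUNTS)
    assert summary["total_edges"] == 4772
    assert summary["shares"] == {
        "beneficial": 23.1,
        "harmful": 14.3,
        "neutral": 62.6,
    }


def test_per_type_counts_sum_to_total(default_graph):
    by_type = defaultdict(int)
    for e in default_graph.edges:
        by_type[e.relation_type] += 1
    assert sum(by_type.values()) == default_graph.n_edges


def test_artifact_roundtrip(tmp_path, fixture_graph):
    from dmhkg.graph_builder import KnowledgeGraph

    fixture_graph.write_artifacts(tmp_path)
    back = KnowledgeGraph.from_artifacts(tmp_path)
    assert {e.key for e in back.edges} == {e.key for e in fixture_graph.edges}
    for e in back.edges:
        orig = fixture_graph.edge(*e.key)
        assert e.frequency == orig.frequency
        assert e.weight == pytest.approx(orig.weight)
        assert e.supporting_docs == orig.supporting_docs
    assert back.node_categories == fixture_graph.node_categories
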