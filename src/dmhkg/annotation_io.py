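"""Parse, validate, and serialize annotated-corpus files.

Annotations arrive in a brat-compatible standoff dialect, one file per
abstract (the document id is the file stem, typically a PubMed id):

* ``T`` lines declare entity mentions: ``Tid<TAB>Category Start End<TAB>Text``
* ``R`` lines declare relation instances: ``Rid<TAB>Type Arg1:Tx Arg2:Ty``
* ``A`` lines attach a polarity attribute: ``Aid<TAB>Polarity Rx value``

Character offsets are 0-based half-open.  When a relation has no ``A`` line,
its polarity defaults to the schema's per-type mapping.  A canonical
JSON-lines format serves as the internal interchange form; parse -> serialize
-> parse is the identity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from ._util import pct
from .schema import POLARITY_CLASSES, SchemaConfig

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A structurally malformed standoff line (reported with line number)."""


class SchemaViolation(ValueError):
    """An annotation referencing a category/type outside the schema."""


class CorpusError(ValueError):
    """Corpus-level problem, e.g. duplicate document ids."""


@dataclass(frozen=True)
class EntityMention:
    doc_id: str
    mention_id: str
    category: str
    surface: str
    span_start: int
    span_end: int

    def __post_init__(self) -> None:
        if self.span_start < 0 or self.span_end <= self.span_start:
            raise ValueError(
                f"{self.doc_id}/{self.mention_id}: invalid span "
                f"[{self.span_start}, {self.span_end})"
            )


@dataclass(frozen=True)
class RelationInstance:
    doc_id: str
    relation_id: str
    relation_type: str
    polarity: str
    source_mention: str
    target_mention: str

    def __post_init__(self) -> None:
        if self.polarity not in POLARITY_CLASSES:
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.source_mention == self.target_mention:
            raise ValueError(
                f"{self.doc_id}/{self.relation_id}: source and target mention "
                "must differ"
            )


@dataclass
class AnnotatedDocument:
    """One abstract's mentions and relations, with provenance."""

    doc_id: str
    mentions: list[EntityMention] = field(default_factory=list)
    relations: list[RelationInstance] = field(default_factory=list)
    issues: list[str] = field(default_factory=list, compare=False)

    def mention_index(self) -> dict[str, EntityMention]:
        return {m.mention_id: m for m in self.mentions}

    def validate(self) -> None:
        """Check id uniqueness and that every relation endpoint resolves."""
        index = self.mention_index()
        if len(index) != len(self.mentions):
            raise CorpusError(f"{self.doc_id}: duplicate mention ids")
        rel_ids = {r.relation_id for r in self.relations}
        if len(rel_ids) != len(self.relations):
            raise CorpusError(f"{self.doc_id}: duplicate relation ids")
        for rel in self.relations:
            for endpoint in (rel.source_mention, rel.target_mention):
                if endpoint not in index:
                    raise CorpusError(
                        f"{self.doc_id}/{rel.relation_id}: dangling endpoint "
                        f"{endpoint!r}"
                    )


@dataclass
class Corpus:
    """A collection of validated documents plus per-file load failures."""

    documents: list[AnnotatedDocument] = field(default_factory=list)
    failures: list[tuple[str, str]] = field(default_factory=list)

    def __iter__(self) -> Iterator[AnnotatedDocument]:
        return iter(self.documents)

    def __len__(self) -> int:
        return len(self.documents)

    @property
    def n_mentions(self) -> int:
        return sum(len(d.mentions) for d in self.documents)

    @property
    def n_relations(self) -> int:
        return sum(len(d.relations) for d in self.documents)

    @property
    def doc_ids(self) -> list[str]:
        return [d.doc_id for d in self.documents]


# ---------------------------------------------------------------------------
# standoff parsing


def _split_fields(line: str, n_head: int) -> list[str]:
    """Split a standoff line into id / body [/ text] fields.

    Tab-delimited is the canonical form; whitespace-only lines (as produced
    by some exporters) are accepted as a fallback, in which case everything
    after the first ``n_head`` tokens is the trailing free-text field.
    """
    if "\t" in line:
        return line.split("\t")
    tokens = line.split()
    if len(tokens) <= n_head:
        return [tokens[0], " ".join(tokens[1:])] if tokens else []
    return [tokens[0], " ".join(tokens[1 : n_head + 1]), " ".join(tokens[n_head:][1:])]


def parse_standoff(
    lines: Iterable[str],
    doc_id: str,
    schema: SchemaConfig | None = None,
    strict: bool = False,
) -> AnnotatedDocument:
    """Parse one document's standoff lines into an :class:`AnnotatedDocument`.

    Malformed lines always raise :class:`ParseError` with the line number.
    Unknown categories/types are schema violations: collected on
    ``doc.issues`` (the offending annotation is dropped) unless ``strict``,
    in which case they raise :class:`SchemaViolation`.
    """
    schema = schema or SchemaConfig()
    doc = AnnotatedDocument(doc_id=doc_id)
    pending_polarity: dict[str, str] = {}
    raw_relations: list[tuple[str, str, str, str]] = []

    def violation(msg: str) -> None:
        if strict:
            raise SchemaViolation(f"{doc_id}: {msg}")
        doc.issues.append(msg)
        logger.warning("%s: %s", doc_id, msg)

    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        tag = line.lstrip()[0]
        try:
            if tag == "T":
                fields = _split_fields(line, n_head=3)
                if len(fields) < 3:
                    raise ValueError("expected 'Tid<TAB>Cat Start End<TAB>Text'")
                mid = fields[0].strip()
                cat_name, start_s, end_s = fields[1].split()
                surface = "\t".join(fields[2:])
                category = schema.resolve_category(cat_name)
                if category is None:
                    violation(f"line {lineno}: unknown category {cat_name!r}")
                    continue
                doc.mentions.append(
                    EntityMention(
                        doc_id=doc_id,
                        mention_id=mid,
                        category=category,
                        surface=surface,
                        span_start=int(start_s),
                        span_end=int(end_s),
                    )
                )
            elif tag == "R":
                fields = line.split("\t") if "\t" in line else line.split(None, 1)
                if len(fields) < 2:
                    raise ValueError("expected 'Rid<TAB>Type Arg1:Tx Arg2:Ty'")
                rid = fields[0].strip()
                rtype, arg1, arg2 = fields[1].split()
                if not (arg1.startswith("Arg1:") and arg2.startswith("Arg2:")):
                    raise ValueError("relation arguments must be Arg1:/Arg2:")
                if rtype not in schema.relation_types:
                    violation(f"line {lineno}: unknown relation type {rtype!r}")
                    continue
                raw_relations.append((rid, rtype, arg1[5:], arg2[5:]))
            elif tag == "A":
                fields = line.split("\t") if "\t" in line else line.split(None, 1)
                if len(fields) < 2:
                    raise ValueError("expected 'Aid<TAB>Polarity Rx value'")
                attr_name, target, value = fields[1].split()
                if attr_name.lower() != "polarity":
                    violation(f"line {lineno}: unknown attribute {attr_name!r}")
                    continue
                if value not in POLARITY_CLASSES:
                    violation(f"line {lineno}: unknown polarity {value!r}")
                    continue
                pending_polarity[target] = value
            else:
                raise ValueError(f"unknown record tag {tag!r}")
        except (ParseError, SchemaViolation):
            raise
        except ValueError as exc:
            raise ParseError(f"{doc_id} line {lineno}: {exc}") from exc

    mention_ids = {m.mention_id for m in doc.mentions}
    for rid, rtype, src, tgt in raw_relations:
        if src not in mention_ids or tgt not in mention_ids:
            violation(f"relation {rid}: endpoint not found ({src}, {tgt})")
            continue
        if src == tgt:
            violation(f"relation {rid}: source equals target mention")
            continue
        polarity = pending_polarity.get(rid, schema.default_polarity(rtype))
        doc.relations.append(
            RelationInstance(
                doc_id=doc_id,
                relation_id=rid,
                relation_type=rtype,
                polarity=polarity,
                source_mention=src,
                target_mention=tgt,
            )
        )
    doc.validate()
    return doc


def write_standoff(doc: AnnotatedDocument, schema: SchemaConfig | None = None) -> str:
    """Render a document back to canonical tab-delimited standoff text.

    ``A`` lines are emitted only where the instance polarity differs from the
    schema default for its type, so parse -> write -> parse round-trips.
    """
    schema = schema or SchemaConfig()
    out: list[str] = []
    for m in doc.mentions:
        out.append(f"{m.mention_id}\t{m.category} {m.span_start} {m.span_end}\t{m.surface}")
    attr_no = 0
    for r in doc.relations:
        out.append(
            f"{r.relation_id}\t{r.relation_type} "
            f"Arg1:{r.source_mention} Arg2:{r.target_mention}"
        )
        if r.polarity != schema.default_polarity(r.relation_type):
            attr_no += 1
            out.append(f"A{attr_no}\tPolarity {r.relation_id} {r.polarity}")
    return "\n".join(out) + ("\n" if out else "")


# ---------------------------------------------------------------------------
# corpus loading


def load_corpus(
    path: str | Path,
    schema: SchemaConfig | None = None,
    strict: bool = False,
    manifest: str | Path | None = None,
) -> Corpus:
    """Load all ``*.ann`` files under ``path`` (one document each).

    Document ids default to file stems; an optional 2-column manifest TSV
    (``filename<TAB>doc_id``) overrides them.  Duplicate doc ids raise
    :class:`CorpusError`.  In non-strict mode a malformed file is recorded as
    a failure and skipped; in strict mode it aborts the load.
    """
    schema = schema or SchemaConfig()
    root = Path(path)
    if not root.exists():
        raise FileNotFoundError(root)
    name_map: dict[str, str] = {}
    if manifest is not None:
        for line in Path(manifest).read_text(encoding="utf-8").splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            fname, did = line.split("\t")
            name_map[fname] = did

    corpus = Corpus()
    seen: set[str] = set()
    for ann_path in sorted(root.glob("*.ann")):
        doc_id = name_map.get(ann_path.name, ann_path.stem)
        if doc_id in seen:
            raise CorpusError(f"duplicate doc_id {doc_id!r}")
        seen.add(doc_id)
        try:
            doc = parse_standoff(
                ann_path.read_text(encoding="utf-8").splitlines(),
                doc_id=doc_id,
                schema=schema,
                strict=strict,
            )
        except (ParseError, SchemaViolation, CorpusError) as exc:
            if strict:
                raise
            corpus.failures.append((ann_path.name, str(exc)))
            logger.warning("skipping %s: %s", ann_path.name, exc)
            continue
        corpus.documents.append(doc)
    logger.info(
        "loaded %d documents (%d mentions, %d relations, %d failures)",
        len(corpus),
        corpus.n_mentions,
        corpus.n_relations,
        len(corpus.failures),
    )
    return corpus


def corpus_summary(corpus: Corpus) -> dict:
    """Per-category mention counts and percentage shares, per-type relation counts."""
    if corpus.n_mentions == 0:
        raise CorpusError("summary undefined for an empty corpus")
    cat_counts: dict[str, int] = {}
    type_counts: dict[str, int] = {}
    for doc in corpus:
        for m in doc.mentions:
            cat_counts[m.category] = cat_counts.get(m.category, 0) + 1
        for r in doc.relations:
            type_counts[r.relation_type] = type_counts.get(r.relation_type, 0) + 1
    total = corpus.n_mentions
    return {
        "n_documents": len(corpus),
        "n_mentions": total,
        "n_relations": corpus.n_relations,
        "category_counts": dict(sorted(cat_counts.items())),
        "category_shares": {
            c: pct(n, total) for c, n in sorted(cat_counts.items())
        },
        "relation_type_counts": dict(sorted(type_counts.items())),
    }


# ---------------------------------------------------------------------------
# canonical JSON-lines interchange


def corpus_to_jsonl(corpus: Corpus, path: str | Path) -> None:
    """Write one record per mention/relation, typed by a ``kind`` field."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for doc in corpus:
            for m in doc.mentions:
                fh.write(
                    json.dumps(
                        {
                            "kind": "mention",
                            "doc_id": m.doc_id,
                            "id": m.mention_id,
                            "category": m.category,
                            "surface": m.surface,
                            "start": m.span_start,
                            "end": m.span_end,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
            for r in doc.relations:
                fh.write(
                    json.dumps(
                        {
                            "kind": "relation",
                            "doc_id": r.doc_id,
                            "id": r.relation_id,
                            "type": r.relation_type,
                            "polarity": r.polarity,
                            "source": r.source_mention,
                            "target": r.target_mention,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )


def corpus_from_jsonl(path: str | Path) -> Corpus:
    docs: dict[str, AnnotatedDocument] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        doc = docs.setdefault(rec["doc_id"], AnnotatedDocument(doc_id=rec["doc_id"]))
        if rec["kind"] == "mention":
            doc.mentions.append(
                EntityMention(
                    doc_id=rec["doc_id"],
                    mention_id=rec["id"],
                    category=rec["category"],
                    surface=rec["surface"],
                    span_start=rec["start"],
                    span_end=rec["end"],
                )
            )
        elif rec["kind"] == "relation":
            doc.relations.append(
                RelationInstance(
                    doc_id=rec["doc_id"],
                    relation_id=rec["id"],
                    relation_type=rec["type"],
                    polarity=rec["polarity"],
                    source_mention=rec["source"],
                    target_mention=rec["target"],
                )
            )
        else:
            raise ParseError(f"unknown record kind {rec['kind']!r}")
    corpus = Corpus(documents=list(docs.values()))
    for doc in corpus:
        doc.validate()
    return corpus
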