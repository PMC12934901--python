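"""Synonym consolidation: unify lexically variant entity labels.

Literature annotation fragments one concept across many surface forms
("SCFA" vs "short-chain fatty acids"; "gut microbiome" / "intestinal flora"
/ "gut microbiota").  Before evidence aggregation, an expert-curated synonym
table maps each variant to one normalized label.  Matching is exact on the
lexically normalized string (case-folded, whitespace-collapsed, optional
trailing-parenthetical stripping) — deliberately not fuzzy, so that only
reviewed merges happen.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

from .annotation_io import AnnotatedDocument, Corpus
from ._util import pct

# a single trailing "(...)" group of at most 10 inner characters, e.g. an
# abbreviation like "Mediterranean diet (MD)"; longer groups are left alone
# to avoid mangling chemical names
_TRAILING_PAREN = re.compile(r"\s*\([^()]{1,10}\)\s*$")
_WS = re.compile(r"\s+")


class SynonymTableError(ValueError):
    """Conflicting or chained entries in a synonym table."""


@dataclass(frozen=True)
class LexicalOptions:
    case_fold: bool = True
    whitespace_collapse: bool = True
    strip_parenthetical: bool = True


def lexical_normalize(surface: str, options: LexicalOptions = LexicalOptions()) -> str:
    """Apply the purely lexical part of normalization to a surface form."""
    text = surface.strip()
    if options.strip_parenthetical:
        text = _TRAILING_PAREN.sub("", text)
    if options.whitespace_collapse:
        text = _WS.sub(" ", text)
    if options.case_fold:
        text = text.casefold()
    return text.strip()


@dataclass
class SynonymMap:
    """Curated normalized-label <- variant-labels mapping.

    Invariants: no variant maps to two normalized labels, and no normalized
    label is itself a variant of another entry (no chains).
    """

    entries: dict[str, set[str]] = field(default_factory=dict)
    options: LexicalOptions = LexicalOptions()

    def __post_init__(self) -> None:
        self._lookup: dict[str, str] = {}
        for normalized in self.entries:
            key = lexical_normalize(normalized, self.options)
            self._lookup[key] = normalized
        for normalized, variants in self.entries.items():
            for variant in variants:
                key = lexical_normalize(variant, self.options)
                existing = self._lookup.get(key)
                if existing is not None and existing != normalized:
                    if key in {
                        lexical_normalize(n, self.options) for n in self.entries
                    }:
                        raise SynonymTableError(
                            f"chain: {variant!r} is a variant of {normalized!r} "
                            f"but also a normalized label ({existing!r})"
                        )
                    raise SynonymTableError(
                        f"conflict: variant {variant!r} maps to both "
                        f"{existing!r} and {normalized!r}"
                    )
                self._lookup[key] = normalized

    @property
    def n_normalized_forms(self) -> int:
        return len(self.entries)

    @property
    def n_variants(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def lookup(self, lexical_key: str) -> str | None:
        return self._lookup.get(lexical_key)

    @classmethod
    def identity(cls, options: LexicalOptions = LexicalOptions()) -> "SynonymMap":
        return cls(entries={}, options=options)


def load_synonym_table(
    path: str | Path, options: LexicalOptions = LexicalOptions()
) -> SynonymMap:
    """Read a 2-column TSV (normalized_label, variant_label); '#' comments allowed."""
    entries: dict[str, set[str]] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise SynonymTableError(
                f"line {lineno}: expected 'normalized<TAB>variant', got {line!r}"
            )
        normalized, variant = parts[0].strip(), parts[1].strip()
        if normalized.lower() in ("normalized_label",) and lineno == 1:
            continue  # optional header row
        entries.setdefault(normalized, set()).add(variant)
    return SynonymMap(entries=entries, options=options)


def write_synonym_table(synmap: SynonymMap, path: str | Path) -> None:
    rows = ["normalized_label\tvariant_label"]
    for normalized in sorted(synmap.entries):
        for variant in sorted(synmap.entries[normalized]):
            rows.append(f"{normalized}\t{variant}")
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def normalize_label(surface: str, synmap: SynonymMap) -> str:
    """Normalize one surface label: lexical options, then table lookup.

    Labels absent from the table pass through lexically normalized.
    """
    key = lexical_normalize(surface, synmap.options)
    return synmap.lookup(key) or key


@dataclass(frozen=True)
class ConsolidationReport:
    mentions_unified: int
    normalized_forms: int
    total_mentions: int

    @property
    def share_unified(self) -> float:
        if self.total_mentions == 0:
            return 0.0
        return pct(self.mentions_unified, self.total_mentions)


def apply_consolidation(
    corpus: Corpus, synmap: SynonymMap
) -> tuple[Corpus, ConsolidationReport]:
    """Rewrite every mention surface to its normalized label.

    A mention counts as *unified* only when the synonym table changed its
    label beyond lexical normalization (pure case/whitespace/parenthetical
    changes are not merges).  Mention counts are conserved; the number of
    distinct labels never increases; the operation is idempotent on the
    corpus.
    """
    unified = 0
    unified_forms: set[str] = set()
    new_docs: list[AnnotatedDocument] = []
    for doc in corpus:
        new_mentions = []
        for m in doc.mentions:
            lexical = lexical_normalize(m.surface, synmap.options)
            normalized = synmap.lookup(lexical) or lexical
            if lexical_normalize(normalized, synmap.options) != lexical:
                unified += 1
                unified_forms.add(normalized)
            new_mentions.append(replace(m, surface=normalized))
        new_docs.append(
            AnnotatedDocument(
                doc_id=doc.doc_id,
                mentions=new_mentions,
                relations=list(doc.relations),
            )
        )
    report = ConsolidationReport(
        mentions_unified=unified,
        normalized_forms=len(unified_forms),
        total_mentions=corpus.n_mentions,
    )
    return Corpus(documents=new_docs, failures=list(corpus.failures)), report
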