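"""Annotation schema configuration: entity categories, relation types, polarity.

The annotation schema distinguishes eleven entity categories and twelve
directional relation types.  Each relation instance carries a polarity label
(beneficial, harmful, or neutral); when no explicit polarity attribute is
annotated, the relation type's default polarity applies.  Polarity classes
map to the multipliers used by the evidence-weighting function
(1.2 beneficial, 1.1 harmful, 1.0 neutral).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

POLARITY_CLASSES = ("beneficial", "harmful", "neutral")

#: Default eleven-category vocabulary.  Category names are configuration, not
#: ground truth: replace them via a YAML schema file if your annotation
#: guideline uses different labels.
DEFAULT_CATEGORIES: tuple[str, ...] = (
    "nutrition",
    "microbiome",
    "metabolite",
    "gene",
    "protein",
    "physiological_process",
    "clinical_outcome",
    "disease",
    "population",
    "intervention",
    "biomarker",
)

#: The twelve directional relation types.
RELATION_TYPES: tuple[str, ...] = (
    "associated_with",
    "affects",
    "causes",
    "regulates",
    "modifies",
    "maintains",
    "assists",
    "benefits",
    "increases",
    "reduces",
    "inhibits",
    "harms",
)

#: Default polarity class per relation type.  Beneficial effects are carried
#: by benefits/increases, harmful ones by reduces/inhibits/harms; the
#: remaining seven types are neutral/observational.
DEFAULT_TYPE_TO_POLARITY: dict[str, str] = {
    "associated_with": "neutral",
    "affects": "neutral",
    "causes": "neutral",
    "regulates": "neutral",
    "modifies": "neutral",
    "maintains": "neutral",
    "assists": "neutral",
    "benefits": "beneficial",
    "increases": "beneficial",
    "reduces": "harmful",
    "inhibits": "harmful",
    "harms": "harmful",
}

DEFAULT_POLARITY_MULTIPLIERS: dict[str, float] = {
    "beneficial": 1.2,
    "harmful": 1.1,
    "neutral": 1.0,
}


class SchemaError(ValueError):
    """Raised when a schema configuration violates its invariants."""


@dataclass(frozen=True)
class SchemaConfig:
    """Vocabulary and polarity configuration for an annotated corpus."""

    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    relation_types: tuple[str, ...] = RELATION_TYPES
    type_to_polarity: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_TO_POLARITY)
    )
    polarity_multipliers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_POLARITY_MULTIPLIERS)
    )

    def __post_init__(self) -> None:
        if len(set(self.categories)) != len(self.categories):
            raise SchemaError("duplicate category ids")
        if set(self.relation_types) != set(RELATION_TYPES):
            raise SchemaError(
                "relation_types must be exactly the twelve configured type ids"
            )
        missing = set(self.relation_types) - set(self.type_to_polarity)
        if missing:
            raise SchemaError(f"type_to_polarity missing types: {sorted(missing)}")
        bad = set(self.type_to_polarity.values()) - set(POLARITY_CLASSES)
        if bad:
            raise SchemaError(f"unknown polarity classes: {sorted(bad)}")
        if set(self.polarity_multipliers) != set(POLARITY_CLASSES):
            raise SchemaError("polarity_multipliers must cover the three classes")
        if any(m <= 0 for m in self.polarity_multipliers.values()):
            raise SchemaError("polarity multipliers must be strictly positive")

    # -- lookups -----------------------------------------------------------

    def resolve_category(self, name: str) -> str | None:
        """Case-insensitive category lookup; returns the canonical id or None."""
        lowered = name.strip().lower()
        for cat in self.categories:
            if cat.lower() == lowered:
                return cat
        return None

    def default_polarity(self, relation_type: str) -> str:
        return self.type_to_polarity[relation_type]

    def multiplier(self, polarity: str) -> float:
        return self.polarity_multipliers[polarity]

    # -- serialization -----------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SchemaConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(
            categories=tuple(data.get("categories", DEFAULT_CATEGORIES)),
            relation_types=tuple(data.get("relation_types", RELATION_TYPES)),
            type_to_polarity=dict(
                data.get("type_to_polarity", DEFAULT_TYPE_TO_POLARITY)
            ),
            polarity_multipliers=dict(
                data.get("polarity_multipliers", DEFAULT_POLARITY_MULTIPLIERS)
            ),
        )

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "categories": list(self.categories),
            "relation_types": list(self.relation_types),
            "type_to_polarity": dict(self.type_to_polarity),
            "polarity_multipliers": dict(self.polarity_multipliers),
        }
        Path(path).write_text(
            yaml.safe_dump(payload, sort_keys=False), encoding="utf-8"
        )
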