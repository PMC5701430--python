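"""Chronic-condition catalog: diagnosis-code patterns and care-complexity classes.

The segmentation framework rests on a roster of chronic conditions, each
carrying ICD-9 and ICD-10 code *prefixes* (adapted from the published
Charlson / Elixhauser administrative-data mappings), optional verbatim
primary-care condition labels, and a care-complexity category:

``stable``
    a chronic condition that by itself does not restrict usual function
    or drive intensive specialist care (e.g. hypertension, asthma);
``complex``
    a condition whose presence defines the complex-chronic segments
    (e.g. diabetes with chronic complications, non-metastatic malignancy);
``terminal``
    a marker of terminal illness that places a patient in the
    End-of-Life segment (default roster: metastatic disease).

Raw codes are resolved to conditions by normalized longest-prefix
matching for the ICD systems and by case-insensitive exact label
matching for primary-care codes.  Every category assignment in the
shipped default catalog can be overridden by supplying a user catalog
file with the same schema.
"""

from __future__ import annotations

import json
from enum import Enum
from functools import lru_cache
from importlib import resources
from typing import Iterable, Iterator, Literal

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import CatalogError

__all__ = [
    "Category",
    "CodeSystem",
    "ConditionDefinition",
    "ConditionCatalog",
    "normalize_code",
    "match_code",
    "load_catalog",
    "default_catalog",
]


class Category(str, Enum):
    """Care-complexity class of a chronic condition."""

    stable = "stable"
    complex = "complex"
    terminal = "terminal"


class CodeSystem(str, Enum):
    """Coding system a raw diagnosis code belongs to."""

    ICD9 = "ICD9"
    ICD10 = "ICD10"
    primary_care = "primary_care"


def normalize_code(code: str) -> str:
    """Normalize a raw ICD code: strip surrounding whitespace and periods, uppercase.

    ICD dialects differ in dotted ("I10.9") versus undotted ("I109")
    forms across EHR exports; matching is performed on the undotted
    uppercase form.
    """
    return code.replace(".", "").strip().upper()


class ConditionDefinition(BaseModel):
    """One chronic condition with its code patterns and complexity class."""

    model_config = ConfigDict(frozen=True)

    name: str
    label: str = ""
    category: Category
    icd9: tuple[str, ...] = ()
    icd10: tuple[str, ...] = ()
    primary_care: tuple[str, ...] = ()
    source: Literal["CDMP", "Charlson", "Elixhauser", "custom"] = "custom"

    @field_validator("icd9", "icd10", mode="after")
    @classmethod
    def _normalize_patterns(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        patterns = tuple(normalize_code(p) for p in v)
        if any(not p for p in patterns):
            raise ValueError("empty code pattern")
        return patterns

    @field_validator("primary_care", mode="after")
    @classmethod
    def _strip_labels(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        labels = tuple(s.strip() for s in v)
        if any(not s for s in labels):
            raise ValueError("empty primary-care label")
        return labels

    @model_validator(mode="after")
    def _at_least_one_pattern(self) -> "ConditionDefinition":
        if not (self.icd9 or self.icd10 or self.primary_care):
            raise ValueError(
                f"condition {self.name!r} has no code patterns and no primary-care labels"
            )
        if not self.label:
            object.__setattr__(self, "label", self.name)
        return self

    def patterns(self, system: CodeSystem) -> tuple[str, ...]:
        if system is CodeSystem.ICD9:
            return self.icd9
        if system is CodeSystem.ICD10:
            return self.icd10
        return self.primary_care


class ConditionCatalog(BaseModel):
    """Ordered, validated collection of :class:`ConditionDefinition`."""

    model_config = ConfigDict(frozen=True)

    conditions: tuple[ConditionDefinition, ...]
    version: str = "unversioned"

    @model_validator(mode="after")
    def _validate(self) -> "ConditionCatalog":
        if not self.conditions:
            raise ValueError("catalog has no conditions")
        names = [c.name for c in self.conditions]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate condition names: {sorted(dupes)}")
        seen: dict[tuple[str, str], str] = {}
        for cond in self.conditions:
            for system in (CodeSystem.ICD9, CodeSystem.ICD10):
                for pat in cond.patterns(system):
                    key = (system.value, pat)
                    if key in seen and seen[key] != cond.name:
                        raise ValueError(
                            f"pattern {pat!r} ({system.value}) is claimed by both "
                            f"{seen[key]!r} and {cond.name!r}"
                        )
                    seen[key] = cond.name
        return self

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.conditions)

    def __iter__(self) -> Iterator[ConditionDefinition]:  # type: ignore[override]
        return iter(self.conditions)

    def __contains__(self, name: object) -> bool:
        return any(c.name == name for c in self.conditions)

    def get(self, name: str) -> ConditionDefinition:
        for c in self.conditions:
            if c.name == name:
                return c
        raise KeyError(name)

    # -- category views ------------------------------------------------------

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.conditions)

    def names_in_category(self, category: Category | str) -> tuple[str, ...]:
        category = Category(category)
        return tuple(c.name for c in self.conditions if c.category is category)

    def category_of(self, name: str) -> Category:
        return self.get(name).category


def match_code(
    code: str,
    system: CodeSystem | str,
    catalog: ConditionCatalog,
) -> frozenset[str]:
    """Resolve one raw diagnosis code to the set of matching condition names.

    ICD-9/ICD-10 codes match a condition when any of the condition's
    patterns is a prefix of the normalized code; primary-care codes match
    by case-insensitive equality with a primary-care label.  The result
    is a (possibly empty) frozen set of condition names and does not
    depend on catalog ordering.
    """
    try:
        system = CodeSystem(system)
    except ValueError:
        raise ValueError(f"unknown code system: {system!r}") from None
    matched: set[str] = set()
    if system is CodeSystem.primary_care:
        key = code.strip().casefold()
        if not key:
            raise ValueError("empty diagnosis code")
        for cond in catalog:
            if any(key == lbl.casefold() for lbl in cond.primary_care):
                matched.add(cond.name)
    else:
        norm = normalize_code(code)
        if not norm:
            raise ValueError("empty diagnosis code")
        for cond in catalog:
            if any(norm.startswith(pat) for pat in cond.patterns(system)):
                matched.add(cond.name)
    return frozenset(matched)


def _parse_catalog_mapping(raw: object, origin: str) -> ConditionCatalog:
    if not isinstance(raw, dict) or "conditions" not in raw:
        raise CatalogError(f"{origin}: expected a mapping with a 'conditions' list")
    entries = raw["conditions"]
    if not isinstance(entries, list):
        raise CatalogError(f"{origin}: 'conditions' must be a list")
    conditions = []
    for i, entry in enumerate(entries):
        ident = entry.get("name", f"#{i}") if isinstance(entry, dict) else f"#{i}"
        try:
            conditions.append(ConditionDefinition.model_validate(entry))
        except Exception as exc:
            raise CatalogError(f"{origin}: bad condition entry {ident!r}: {exc}") from exc
    try:
        return ConditionCatalog(
            conditions=tuple(conditions),
            version=str(raw.get("version", "unversioned")),
        )
    except Exception as exc:
        raise CatalogError(f"{origin}: {exc}") from exc


def load_catalog(path) -> ConditionCatalog:
    """Load and validate a condition catalog from a JSON or YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    try:
        raw = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as exc:
        raise CatalogError(f"{path}: cannot parse catalog file: {exc}") from exc
    return _parse_catalog_mapping(raw, str(path))


@lru_cache(maxsize=1)
def default_catalog() -> ConditionCatalog:
    """The built-in 34-condition catalog shipped with the package.

    The roster covers the chronic-disease list of the Singapore Chronic
    Disease Management Program augmented with Charlson and Elixhauser
    comorbidities; code prefixes are adapted from the published Quan et
    al. administrative-code mappings.
    """
    text = resources.files("popseg").joinpath("data/default_catalog.json").read_text("utf-8")
    return _parse_catalog_mapping(json.loads(text), "default_catalog.json")


def conditions_table(catalog: ConditionCatalog) -> "list[dict]":
    """Flat summary of a catalog, one dict per condition (for reports)."""
    return [
        {
            "name": c.name,
            "label": c.label,
            "category": c.category.value,
            "n_icd9": len(c.icd9),
            "n_icd10": len(c.icd10),
            "source": c.source,
        }
        for c in catalog
    ]
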