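"""Chronic-condition catalog: ATC patterns grouped into disease categories.

A :class:`Catalog` maps dispensed drug codes to chronic-condition
categories.  Each category has inclusion patterns (prefix or exact),
optional exclusion patterns (exclusion wins), optional ``all_of_groups``
(component code groups that must each be chronically present, used for
chronic heart failure) and a total priority order used to resolve codes
that match more than one category.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .atc import ATCPattern, InvalidATCError, is_valid_atc, require_full_code

BUILTIN_CATALOGS = {"rxriskv_mod_2010"}

#: Category name used for the all-of (loop diuretic + ACE inhibitor) rule.
CHF_CATEGORY = "Chronic Heart failure"


class CatalogSchemaError(ValueError):
    """Raised when a catalog document violates the catalog schema."""


@dataclass(frozen=True)
class ConditionCategory:
    """One chronic-condition category and its drug-code patterns."""

    name: str
    includes: frozenset[ATCPattern]
    excludes: frozenset[ATCPattern] = frozenset()
    all_of_groups: tuple[frozenset[ATCPattern], ...] = ()
    priority_rank: int = 0
    concordant: bool = False
    #: printed literals that violate the ATC grammar, kept verbatim for linting
    nonconforming: Mapping[str, str] = field(default_factory=dict)

    def match_code(self, code: str) -> bool:
        """True iff the full ATC *code* matches an include and no exclude.

        Exclusion takes precedence over inclusion.  Raises for truncated
        or malformed query codes; patterns, in contrast, may be truncated.
        """
        code = require_full_code(code)
        if any(p.matches(code) for p in self.excludes):
            return False
        return any(p.matches(code) for p in self.includes)


@dataclass(frozen=True)
class Catalog:
    """An ordered, validated collection of condition categories."""

    categories: tuple[ConditionCategory, ...]
    version: str = "custom"

    def __post_init__(self) -> None:
        names = [c.name for c in self.categories]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise CatalogSchemaError(f"duplicate category name(s): {dupes}")
        ranks = [c.priority_rank for c in self.categories]
        if len(set(ranks)) != len(ranks):
            raise CatalogSchemaError("priority_rank values must form a total order (no ties)")

    def __len__(self) -> int:
        return len(self.categories)

    def __getitem__(self, name: str) -> ConditionCategory:
        for c in self.categories:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.categories]

    def by_priority(self) -> list[ConditionCategory]:
        return sorted(self.categories, key=lambda c: c.priority_rank)

    def categories_for_code(self, code: str) -> list[str]:
        """Names of all categories matching *code*, highest priority first."""
        code = require_full_code(code)
        return [c.name for c in self.by_priority() if c.match_code(code)]

    def resolve_code(self, code: str) -> str | None:
        """Single category a code is attributed to (highest-priority match)."""
        matches = self.categories_for_code(code)
        return matches[0] if matches else None


def _parse_patterns(raw: Iterable[str], *, where: str) -> frozenset[ATCPattern]:
    patterns = []
    for entry in raw:
        try:
            patterns.append(ATCPattern(str(entry).strip().upper()))
        except InvalidATCError as exc:
            raise CatalogSchemaError(f"malformed ATC code {entry!r} in {where}: {exc}") from exc
    return frozenset(patterns)


def _parse_category(doc: Mapping, *, apply_corrections: bool) -> ConditionCategory:
    if "name" not in doc or not str(doc["name"]).strip():
        raise CatalogSchemaError("category without a name")
    name = str(doc["name"]).strip()
    includes = list(doc.get("includes") or [])
    nonconforming = {str(k): str(v) for k, v in (doc.get("nonconforming") or {}).items()}
    for literal, intended in nonconforming.items():
        if is_valid_atc(literal):
            raise CatalogSchemaError(
                f"{literal!r} in {name} is listed as nonconforming but is grammatical"
            )
        if not is_valid_atc(intended):
            raise CatalogSchemaError(f"intended correction {intended!r} in {name} is malformed")
        if apply_corrections:
            includes.append(intended)
    return ConditionCategory(
        name=name,
        includes=_parse_patterns(includes, where=f"includes of {name}"),
        excludes=_parse_patterns(doc.get("excludes") or [], where=f"excludes of {name}"),
        all_of_groups=tuple(
            _parse_patterns(group, where=f"all_of_groups of {name}")
            for group in (doc.get("all_of_groups") or [])
        ),
        priority_rank=int(doc.get("priority_rank", 0)),
        concordant=bool(doc.get("concordant", False)),
        nonconforming=nonconforming,
    )


def load_catalog(source: str | Path = "rxriskv_mod_2010", *, apply_corrections: bool = True) -> Catalog:
    """Load a catalog from a built-in identifier or a YAML file path.

    With ``apply_corrections`` (the default) the plausibly intended
    grammatical forms of printed nonconforming literals are added to the
    include sets; the verbatim literals are always retained for linting.
    """
    if isinstance(source, str) and source in BUILTIN_CATALOGS:
        ref = importlib.resources.files("rxcomorbid").joinpath(f"data/{source}.yaml")
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(source).read_text(encoding="utf-8")
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping) or "categories" not in doc:
        raise CatalogSchemaError("catalog document must be a mapping with a 'categories' list")
    raw_categories = doc["categories"]
    if not raw_categories:
        raise CatalogSchemaError("catalog contains no categories")
    categories = tuple(
        _parse_category(c, apply_corrections=apply_corrections) for c in raw_categories
    )
    return Catalog(categories=categories, version=str(doc.get("version", "custom")))


def dump_catalog(catalog: Catalog, path: str | Path) -> None:
    """Serialize a catalog to YAML such that :func:`load_catalog` round-trips.

    Corrected forms of nonconforming literals are not re-serialized (they
    are re-derived at load time), so dump→load is the identity for
    catalogs loaded with the default settings.
    """
    doc = {
        "version": catalog.version,
        "categories": [
            {
                "name": c.name,
                "priority_rank": c.priority_rank,
                "concordant": c.concordant,
                "includes": sorted(
                    p.code
                    for p in c.includes
                    if p.code not in set(c.nonconforming.values())
                ),
                "excludes": sorted(p.code for p in c.excludes),
                "all_of_groups": [sorted(p.code for p in g) for g in c.all_of_groups],
                "nonconforming": dict(c.nonconforming),
            }
            for c in catalog.categories
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


@dataclass(frozen=True)
class LintReport:
    """Deterministic catalog diagnostics."""

    #: pattern -> sorted category names, for patterns used by >1 category
    ambiguous_patterns: dict[str, list[str]]
    #: (category, pattern) exclude entries shadowed by no include
    unshadowed_excludes: list[tuple[str, str]]
    #: (category, literal) entries violating the ATC grammar
    nonconforming_literals: list[tuple[str, str]]

    @property
    def is_clean(self) -> bool:
        return not (
            self.ambiguous_patterns or self.unshadowed_excludes or self.nonconforming_literals
        )


def lint_catalog(catalog: Catalog) -> LintReport:
    """Report pattern ambiguities, dead excludes and ungrammatical literals."""
    by_pattern: dict[str, list[str]] = {}
    for cat in catalog.categories:
        for p in cat.includes:
            by_pattern.setdefault(p.code, []).append(cat.name)
    ambiguous = {
        code: sorted(names) for code, names in sorted(by_pattern.items()) if len(names) > 1
    }

    unshadowed = []
    for cat in catalog.categories:
        for exc in sorted(p.code for p in cat.excludes):
            # an exclude is meaningful only if some include could match a
            # code the exclude also matches: one must prefix the other
            shadowing = any(
                exc.startswith(inc.code) or inc.code.startswith(exc)
                for inc in cat.includes
            )
            if not shadowing:
                unshadowed.append((cat.name, exc))

    nonconforming = sorted(
        (cat.name, literal)
        for cat in catalog.categories
        for literal in cat.nonconforming
    )
    return LintReport(
        ambiguous_patterns=ambiguous,
        unshadowed_excludes=sorted(unshadowed),
        nonconforming_literals=nonconforming,
    )
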