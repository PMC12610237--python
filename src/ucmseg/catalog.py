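"""Chronic-condition registry, ICD-10 code matching, and the Charlson index.

The condition catalog is a plain CSV data file (one row per chronic condition,
prefix-based ICD-10 matching), so a deployment can swap in its own registry
without touching code.  Matching works on *canonical* codes: uppercase,
undotted, whitespace-stripped.  A condition is present when any diagnosis code
falls under one of its prefixes; a subset of prefixes additionally marks the
advanced stage of the condition (e.g. diabetes with renal complications).

The Charlson Comorbidity Index (CCI) uses the Quan ICD-10 coding algorithm
with the classic 1/2/3/6 weights, shipped as a second replaceable CSV.  Each
comorbidity category counts once, and the three classic hierarchy rules apply
(a severe form suppresses its mild form).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple

__all__ = [
    "ConditionEntry",
    "ConditionCatalog",
    "CciWeightTable",
    "ConditionMatches",
    "CatalogError",
    "InvalidCodeError",
    "normalise_icd10",
    "is_mental_health_code",
    "match_conditions",
    "compute_cci",
    "load_catalog",
    "write_catalog",
    "default_catalog",
    "load_cci_table",
    "default_cci_table",
]

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]{0,4}$")
_PREFIX_RE = re.compile(r"^[A-Z][0-9]{2,3}$")

#: severe category -> mild category it suppresses (classic Charlson hierarchy)
_CCI_HIERARCHY = {
    "diabetes_complicated": "diabetes_uncomplicated",
    "severe_liver": "mild_liver",
    "metastatic": "malignancy",
}


class CatalogError(ValueError):
    """Malformed or invariant-violating catalog / weight-table input."""


class InvalidCodeError(ValueError):
    """A diagnosis code that cannot be normalised to ICD-10 shape."""


def normalise_icd10(code: str) -> str:
    """Canonicalise a raw ICD-10 code: strip, uppercase, drop the dot.

    >>> normalise_icd10("e11.21")
    'E1121'
    """
    if not isinstance(code, str) or not code.strip():
        raise InvalidCodeError("empty ICD-10 code")
    canon = code.strip().upper().replace(".", "")
    if not _CODE_RE.match(canon):
        raise InvalidCodeError(f"not an ICD-10-shaped code: {code!r}")
    return canon


def is_mental_health_code(code: str, mental_range: tuple[str, str] = ("F00", "F99")) -> bool:
    """True iff the code's 3-character category lies in the configured range.

    The default range F00–F99 covers the ICD-10 mental and behavioural
    disorders chapter.
    """
    lo, hi = mental_range
    cat = code[:3]
    return len(code) >= 3 and lo <= cat <= hi and cat[0] == lo[0]


@dataclass(frozen=True)
class ConditionEntry:
    """One chronic condition: identifying prefixes plus advanced-stage markers."""

    condition_id: str
    name: str
    icd10_prefixes: tuple[str, ...]
    advanced_marker_prefixes: tuple[str, ...] = ()
    cci_weight: int | None = None

    def __post_init__(self) -> None:
        if not self.condition_id:
            raise CatalogError("condition_id must be non-empty")
        if not self.icd10_prefixes:
            raise CatalogError(f"{self.condition_id}: needs at least one ICD-10 prefix")
        for p in (*self.icd10_prefixes, *self.advanced_marker_prefixes):
            if not _PREFIX_RE.match(p):
                raise CatalogError(
                    f"{self.condition_id}: prefix {p!r} must be a letter + 2-3 digits"
                )
        if self.cci_weight is not None and self.cci_weight < 0:
            raise CatalogError(f"{self.condition_id}: cci_weight must be non-negative")

    @property
    def all_prefixes(self) -> tuple[str, ...]:
        """Prefixes that register this condition (base plus advanced markers)."""
        return tuple(dict.fromkeys(self.icd10_prefixes + self.advanced_marker_prefixes))


@dataclass(frozen=True)
class ConditionCatalog:
    """Validated registry of chronic conditions; prefixes unique across entries."""

    entries: tuple[ConditionEntry, ...]
    version: str = "unversioned"
    # prefix -> (condition_id, is_advanced_marker); built eagerly for fast lookup
    _index: dict[str, tuple[str, bool]] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.entries:
            raise CatalogError("catalog must contain at least one condition")
        ids = [e.condition_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise CatalogError("duplicate condition_id in catalog")
        index: dict[str, tuple[str, bool]] = {}
        for entry in self.entries:
            advanced = set(entry.advanced_marker_prefixes)
            for prefix in entry.all_prefixes:
                owner = index.get(prefix)
                if owner is not None and owner[0] != entry.condition_id:
                    raise CatalogError(
                        f"prefix {prefix!r} appears under both {owner[0]!r} "
                        f"and {entry.condition_id!r}"
                    )
                index[prefix] = (entry.condition_id, prefix in advanced)
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, condition_id: str) -> ConditionEntry:
        for entry in self.entries:
            if entry.condition_id == condition_id:
                return entry
        raise KeyError(condition_id)

    def lookup(self, code: str) -> tuple[str, bool] | None:
        """Longest-prefix lookup of a canonical code.

        Returns ``(condition_id, hit_is_advanced_marker)`` or None. A code that
        equals or extends an advanced-marker prefix counts as advanced even when
        a shorter base prefix also matches.
        """
        best: tuple[str, bool] | None = None
        for k in range(min(len(code), 4), 2, -1):  # prefixes are 3-4 chars
            hit = self._index.get(code[:k])
            if hit is not None:
                best = hit
                break
        if best is None:
            return None
        cond_id, advanced = best
        if not advanced:
            # a longer advanced marker of the same condition may still cover the code
            entry = self.get(cond_id)
            advanced = any(code.startswith(m) for m in entry.advanced_marker_prefixes)
        return cond_id, advanced


class ConditionMatches(NamedTuple):
    """Outcome of matching a code list against a catalog."""

    present: dict[str, bool]  # condition_id -> any advanced-marker hit
    unmatched: tuple[str, ...]  # canonical codes with no catalog prefix


def match_conditions(codes: Iterable[str], catalog: ConditionCatalog) -> ConditionMatches:
    """Map canonical ICD-10 codes to the chronic conditions they indicate.

    Idempotent and order/duplication-invariant: the result depends only on the
    set of distinct codes.  Unmatched codes are returned for the diagnostics
    tally, never raised.
    """
    present: dict[str, bool] = {}
    unmatched: list[str] = []
    for code in sorted(set(codes)):
        hit = catalog.lookup(code)
        if hit is None:
            unmatched.append(code)
        else:
            cond_id, advanced = hit
            present[cond_id] = present.get(cond_id, False) or advanced
    return ConditionMatches(present, tuple(unmatched))


# ---------------------------------------------------------------------------
# Charlson Comorbidity Index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CciWeightTable:
    """Prefix -> (weight, category) mapping for the Charlson index."""

    weights: dict[str, tuple[int, str]]
    version: str = "quan-classic"

    def __post_init__(self) -> None:
        for prefix, (weight, _cat) in self.weights.items():
            if not _PREFIX_RE.match(prefix):
                raise CatalogError(f"CCI prefix {prefix!r} must be letter + 2-3 digits")
            if weight not in (1, 2, 3, 6):
                raise CatalogError(f"CCI weight for {prefix} must be in {{1,2,3,6}}")

    def lookup(self, code: str) -> tuple[int, str] | None:
        for k in (4, 3):
            hit = self.weights.get(code[:k])
            if hit is not None:
                return hit
        return None


def compute_cci(codes: Iterable[str], weights: CciWeightTable) -> int:
    """Charlson Comorbidity Index over canonical ICD-10 codes.

    Each comorbidity category counts once regardless of how many codes hit it;
    a severe form suppresses its mild counterpart (complicated diabetes over
    uncomplicated, moderate/severe liver disease over mild, metastatic solid
    tumour over localised malignancy).
    """
    by_category: dict[str, int] = {}
    for code in set(codes):
        hit = weights.lookup(code)
        if hit is not None:
            weight, category = hit
            by_category[category] = weight
    for severe, mild in _CCI_HIERARCHY.items():
        if severe in by_category:
            by_category.pop(mild, None)
    return sum(by_category.values())


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _split_prefixes(raw: str) -> tuple[str, ...]:
    return tuple(p.strip().upper() for p in raw.split(";") if p.strip())


def load_catalog(path: str | Path, expected_entries: int | None = None) -> ConditionCatalog:
    """Read a condition catalog CSV (see data/chronic_conditions.csv for the schema).

    Lines starting with ``#`` are comments.  Raises :class:`CatalogError`
    naming the offending line on malformed rows, and on any invariant
    violation (duplicate prefix, empty catalog).
    """
    path = Path(path)
    entries: list[ConditionEntry] = []
    with path.open(newline="", encoding="utf-8") as fh:
        clean = (line for line in fh if not line.lstrip().startswith("#"))
        reader = csv.DictReader(clean)
        required = {"condition_id", "name", "icd10_prefixes", "advanced_marker_prefixes",
                    "cci_weight"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise CatalogError(f"{path}: header must contain {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                weight = row["cci_weight"].strip()
                entries.append(ConditionEntry(
                    condition_id=row["condition_id"].strip(),
                    name=row["name"].strip(),
                    icd10_prefixes=_split_prefixes(row["icd10_prefixes"]),
                    advanced_marker_prefixes=_split_prefixes(row["advanced_marker_prefixes"]),
                    cci_weight=int(weight) if weight else None,
                ))
            except (CatalogError, ValueError) as exc:
                raise CatalogError(f"{path} line {lineno}: {exc}") from exc
    catalog = ConditionCatalog(tuple(entries), version=path.stem)
    if expected_entries is not None and len(catalog) != expected_entries:
        raise CatalogError(
            f"{path}: expected {expected_entries} conditions, found {len(catalog)}"
        )
    return catalog


def write_catalog(catalog: ConditionCatalog, path: str | Path) -> None:
    """Write a catalog back to CSV; inverse of :func:`load_catalog`."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["condition_id", "name", "icd10_prefixes",
                         "advanced_marker_prefixes", "cci_weight"])
        for e in catalog.entries:
            writer.writerow([
                e.condition_id, e.name,
                ";".join(e.icd10_prefixes), ";".join(e.advanced_marker_prefixes),
                "" if e.cci_weight is None else e.cci_weight,
            ])


def load_cci_table(path: str | Path) -> CciWeightTable:
    """Read a ``prefix,weight,category`` CSV into a weight table."""
    path = Path(path)
    weights: dict[str, tuple[int, str]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        clean = (line for line in fh if not line.lstrip().startswith("#"))
        reader = csv.DictReader(clean)
        if reader.fieldnames is None or not {"prefix", "weight", "category"}.issubset(
                reader.fieldnames):
            raise CatalogError(f"{path}: header must contain prefix,weight,category")
        for lineno, row in enumerate(reader, start=2):
            prefix = row["prefix"].strip().upper()
            if prefix in weights:
                raise CatalogError(f"{path} line {lineno}: duplicate prefix {prefix}")
            try:
                weights[prefix] = (int(row["weight"]), row["category"].strip())
            except ValueError as exc:
                raise CatalogError(f"{path} line {lineno}: {exc}") from exc
    return CciWeightTable(weights, version=path.stem)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("ucmseg").joinpath("data", name)))


def default_catalog() -> ConditionCatalog:
    """The shipped 38-condition registry."""
    return load_catalog(_data_path("chronic_conditions.csv"), expected_entries=38)


def default_cci_table() -> CciWeightTable:
    """The shipped Quan ICD-10 Charlson mapping with classic weights."""
    return load_cci_table(_data_path("cci_quan.csv"))
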