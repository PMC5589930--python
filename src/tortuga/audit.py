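"""Data-quality audit of a flat survey dataset.

Legacy paper-forms datasets accumulate three error classes once typed into
a spreadsheet: *missing values* in relevant fields (the nest position, the
time of the record, the recorder's name, the nest id), *variant text* —
different spellings for the same user or the same false-crawl reason — and
*inconsistent data* (an egg total that does not match the sum of its
partial counts; coordinates outside the survey region).  The audit counts
each class per field/rule and as a union of records, where a record with
several errors counts once, and derives the error-free and per-person
statistics used to compare recording methodologies.

Percentages are reported to one decimal, rounding halves away from zero.
"""

from __future__ import annotations

import difflib
import json
import math
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .records import (AKUMAL_BOUNDS, Coordinates, RegionBounds,
                      check_egg_partition)
from .registry import CATEGORIES, Registry

__all__ = [
    "BOOKKEEPING_COLUMNS",
    "DEFAULT_MISSING_MARKERS",
    "Dataset",
    "RelevantField",
    "AuditConfig",
    "AuditReport",
    "VariantScan",
    "round1",
    "find_missing",
    "find_variant_text",
    "find_inconsistent",
    "find_duplicate_tags",
    "audit",
    "category_field_stats",
    "category_record_counts",
    "suggest_aliases",
]

#: Non-variable columns carried by every flat dataset.
BOOKKEEPING_COLUMNS = ("record_id", "record_category", "recorder")

#: Cell values treated as absent (case-insensitive, whitespace-stripped).
DEFAULT_MISSING_MARKERS = ("", "-", "?", "NA", "N/A")

#: Record categories of a flat dataset (the four completeness-analysis
#: categories plus post-hatch excavations).
RECORD_CATEGORIES = CATEGORIES + ("NEST_EXCAVATED",)


def round1(x: float) -> float:
    """Round to one decimal, halves away from zero (55 -> 9.8% of 561)."""
    if x >= 0:
        return math.floor(x * 10 + 0.5) / 10
    return -math.floor(-x * 10 + 0.5) / 10


# --------------------------------------------------------------------------
# containers


@dataclass
class Dataset:
    """Flat table of survey records: one row per record, one column per
    logical variable, plus bookkeeping columns (id, category, recorder)."""

    df: pd.DataFrame
    source_label: str = ""
    extra_columns: dict = dc_field(default_factory=dict)
    raw: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.df = self.df.astype("string").fillna("")

    @property
    def n(self) -> int:
        return len(self.df)

    def ids(self) -> list:
        return list(self.df.index)

    def copy(self) -> "Dataset":
        return Dataset(self.df.copy(), self.source_label,
                       dict(self.extra_columns),
                       None if self.raw is None else self.raw.copy())


@dataclass(frozen=True)
class RelevantField:
    """An audited field; *columns* lists the dataset columns it spans
    (the nest position spans latitude and longitude — the field is missing
    when any constituent column is missing)."""

    name: str
    columns: tuple[str, ...]
    label: str = ""


@dataclass
class AuditConfig:
    relevant_fields: list[RelevantField]
    alias_maps: dict[str, dict[str, list[str]]]
    region_bounds: RegionBounds = AKUMAL_BOUNDS
    missing_markers: tuple[str, ...] = DEFAULT_MISSING_MARKERS

    def __post_init__(self) -> None:
        if not self.relevant_fields:
            raise ValueError("relevant_fields must be non-empty")
        for column, amap in self.alias_maps.items():
            seen: dict[str, str] = {}
            for canonical, variants in amap.items():
                for v in variants:
                    key = _norm(v)
                    if key in seen and seen[key] != canonical:
                        raise ValueError(
                            f"alias {v!r} of column {column!r} maps to both "
                            f"{seen[key]!r} and {canonical!r}"
                        )
                    seen[key] = canonical

    @classmethod
    def default(cls) -> "AuditConfig":
        p = resources.files("tortuga").joinpath("data/audit_config.json")
        return cls.from_json(json.loads(p.read_text()))

    @classmethod
    def from_json(cls, doc: Mapping) -> "AuditConfig":
        rb = doc.get("region_bounds", {})
        bounds = (RegionBounds(rb["lat_min"], rb["lat_max"], rb["lon_min"],
                               rb["lon_max"]) if rb else AKUMAL_BOUNDS)
        return cls(
            relevant_fields=[
                RelevantField(d["name"], tuple(d["columns"]),
                              d.get("label", d["name"]))
                for d in doc["relevant_fields"]
            ],
            alias_maps={k: {c: list(v) for c, v in m.items()}
                        for k, m in doc.get("alias_maps", {}).items()},
            region_bounds=bounds,
            missing_markers=tuple(doc.get("missing_markers",
                                          DEFAULT_MISSING_MARKERS)),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "AuditConfig":
        return cls.from_json(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class Stat:
    count: int
    percent: Optional[float]  # None when the dataset is empty


@dataclass
class VariantScan:
    flagged: set
    unmapped: set


@dataclass
class AuditReport:
    """Per-class counts and union statistics of one audited dataset."""

    source_label: str
    total_rows: int
    recorders: int
    per_field_missing: dict[str, Stat]
    missing_union: Stat
    variant_text: dict[str, Stat]
    variant_union: Stat
    inconsistent: dict[str, Stat]
    inconsistent_union: Stat
    any_error: Stat
    error_free: Stat
    error_free_per_person: Optional[float]
    records_per_person: Optional[float]
    unmapped_text: dict[str, int] = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        def stat(s: Stat) -> dict:
            return {"count": s.count, "percent": s.percent}

        return {
            "source_label": self.source_label,
            "total_rows": self.total_rows,
            "recorders": self.recorders,
            "per_field_missing": {k: stat(v)
                                  for k, v in self.per_field_missing.items()},
            "missing_union": stat(self.missing_union),
            "variant_text": {k: stat(v) for k, v in self.variant_text.items()},
            "variant_union": stat(self.variant_union),
            "inconsistent": {k: stat(v) for k, v in self.inconsistent.items()},
            "inconsistent_union": stat(self.inconsistent_union),
            "any_error": stat(self.any_error),
            "error_free": stat(self.error_free),
            "error_free_per_person": self.error_free_per_person,
            "records_per_person": self.records_per_person,
            "unmapped_text": dict(self.unmapped_text),
        }

    def to_json(self, indent: int = 1) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self) -> str:
        """Human-readable report mirroring the per-class/union layout."""
        def pct(s: Stat) -> str:
            return "undefined" if s.percent is None else f"{s.percent}%"

        lines = [
            f"Audit of {self.source_label or 'dataset'}",
            f"Total records: {self.total_rows}  "
            f"(field effort: {self.recorders} "
            f"{'person' if self.recorders == 1 else 'people'})",
            "",
            "1. Missing value for relevant fields:",
        ]
        for name, s in self.per_field_missing.items():
            lines.append(f"   {name}: {s.count}  {pct(s)}")
        lines.append(f"   Total (union): {self.missing_union.count}  "
                     f"{pct(self.missing_union)}")
        lines.append("2. Different answers for the same value:")
        for name, s in self.variant_text.items():
            lines.append(f"   {name}: {s.count}  {pct(s)}")
        lines.append(f"   Total (union): {self.variant_union.count}  "
                     f"{pct(self.variant_union)}")
        lines.append("3. Inconsistent data:")
        for name, s in self.inconsistent.items():
            lines.append(f"   {name}: {s.count}  {pct(s)}")
        lines.append(f"   Total (union): {self.inconsistent_union.count}  "
                     f"{pct(self.inconsistent_union)}")
        lines += [
            "",
            f"Records with errors (union): {self.any_error.count}  "
            f"{pct(self.any_error)}",
            f"Records without errors: {self.error_free.count}  "
            f"{pct(self.error_free)}",
            f"Records without errors per person: "
            f"{self.error_free_per_person}",
        ]
        return "\n".join(lines)


# --------------------------------------------------------------------------
# cell predicates


def _norm(text: str) -> str:
    return " ".join(str(text).strip().split()).casefold()


def _missing_mask(series_or_none, index,
                  markers: Sequence[str]) -> pd.Series:
    marks = {_norm(m) for m in markers}
    if series_or_none is None:
        return pd.Series(True, index=index)
    return series_or_none.map(lambda c: _norm(c) in marks)


def _to_float(cell: str) -> Optional[float]:
    try:
        return float(str(cell).strip())
    except (TypeError, ValueError):
        return None


# --------------------------------------------------------------------------
# finders


def find_missing(dataset: Dataset, config: AuditConfig) -> dict[str, set]:
    """Record-id sets with a missing value, per relevant field.

    A field spanning several columns is missing when any of them is; an
    absent column counts as missing for every row.
    """
    out: dict[str, set] = {}
    for rf in config.relevant_fields:
        mask = pd.Series(False, index=dataset.df.index)
        for col in rf.columns:
            series = dataset.df[col] if col in dataset.df.columns else None
            mask |= _missing_mask(series, dataset.df.index,
                                  config.missing_markers)
        out[rf.name] = set(dataset.df.index[mask])
    return out


def find_variant_text(dataset: Dataset, field: str,
                      alias_map: Mapping[str, Iterable[str]],
                      missing_markers: Sequence[str] = DEFAULT_MISSING_MARKERS,
                      ) -> VariantScan:
    """Rows whose non-missing cell is a known variant of a canonical value.

    Comparison is case-insensitive and whitespace-collapsed; a cell equal
    to the canonical form is never flagged.  Cells matching neither a
    canonical nor a variant go to the ``unmapped`` side channel.
    """
    if field not in dataset.df.columns:
        raise KeyError(f"column {field!r} not in dataset")
    canon = {_norm(c) for c in alias_map}
    variants = {_norm(v): c for c, vs in alias_map.items() for v in vs}
    flagged: set = set()
    unmapped: set = set()
    missing = _missing_mask(dataset.df[field], dataset.df.index,
                            missing_markers)
    for idx, cell in dataset.df[field].items():
        if missing.loc[idx]:
            continue
        key = _norm(cell)
        if key in canon:
            continue
        if key in variants:
            flagged.add(idx)
        else:
            unmapped.add(idx)
    return VariantScan(flagged=flagged, unmapped=unmapped)


def _egg_mismatch_ids(dataset: Dataset, markers: Sequence[str]) -> set:
    cols = ("total_eggs", "n_incubated", "n_yolkless", "n_multiyolked",
            "clutch_complete")
    if any(c not in dataset.df.columns for c in cols):
        return set()
    out: set = set()
    for idx, row in dataset.df[list(cols)].iterrows():
        complete = _norm(row["clutch_complete"]) in ("yes", "y", "true", "1")
        vals = [_to_float(row[c]) for c in cols[:4]]
        parsed = [None if v is None else v for v in vals]
        try:
            verdict = check_egg_partition(parsed[0], parsed[1], parsed[2],
                                          parsed[3], complete)
        except ValueError:
            verdict = "mismatch"  # negative counts are inconsistent data
        if verdict == "mismatch":
            out.add(idx)
    return out


def _gps_range_ids(dataset: Dataset, bounds: RegionBounds,
                   markers: Sequence[str]) -> set:
    if ("nest_latitude" not in dataset.df.columns
            or "nest_longitude" not in dataset.df.columns):
        return set()
    out: set = set()
    lat_missing = _missing_mask(dataset.df["nest_latitude"],
                                dataset.df.index, markers)
    lon_missing = _missing_mask(dataset.df["nest_longitude"],
                                dataset.df.index, markers)
    for idx in dataset.df.index:
        if lat_missing.loc[idx] or lon_missing.loc[idx]:
            continue  # counted by the missing-value class instead
        lat = _to_float(dataset.df.at[idx, "nest_latitude"])
        lon = _to_float(dataset.df.at[idx, "nest_longitude"])
        if lat is None or lon is None:
            out.add(idx)  # present but unparseable: inconsistent
        elif not bounds.contains(lat, lon):
            out.add(idx)
    return out


def find_inconsistent(dataset: Dataset,
                      config: AuditConfig) -> dict[str, set]:
    """Record-id sets per inconsistency rule (egg partition, GPS range)."""
    return {
        "egg_sum_mismatch": _egg_mismatch_ids(dataset,
                                              config.missing_markers),
        "gps_out_of_range": _gps_range_ids(dataset, config.region_bounds,
                                           config.missing_markers),
    }


def find_duplicate_tags(dataset: Dataset,
                        markers: Sequence[str] = DEFAULT_MISSING_MARKERS,
                        ) -> dict[str, list]:
    """Nest tags appearing on more than one nest-creation record."""
    if "nest_tag" not in dataset.df.columns:
        return {}
    df = dataset.df
    if "record_category" in df.columns:
        df = df[df["record_category"] == "NEST_SEEN"]
    missing = _missing_mask(df["nest_tag"], df.index, markers)
    groups: dict[str, list] = {}
    for idx, tag in df["nest_tag"][~missing].items():
        groups.setdefault(str(tag), []).append(idx)
    return {t: ids for t, ids in groups.items() if len(ids) > 1}


# --------------------------------------------------------------------------
# the audit


def _recorder_count(dataset: Dataset, config: AuditConfig) -> int:
    if "recorder" in dataset.df.columns:
        vals = {v for v in dataset.df["recorder"]
                if _norm(v) not in {_norm(m) for m in config.missing_markers}}
        return len(vals)
    amap = config.alias_maps.get("user_name", {})
    variants = {_norm(v): c for c, vs in amap.items() for v in vs}
    canon = {_norm(c): c for c in amap}
    names: set[str] = set()
    if "user_name" in dataset.df.columns:
        for cell in dataset.df["user_name"]:
            key = _norm(cell)
            if key in {_norm(m) for m in config.missing_markers}:
                continue
            names.add(canon.get(key) or variants.get(key) or key)
    return len(names)


def audit(dataset: Dataset,
          config: Optional[AuditConfig] = None) -> AuditReport:
    """Full quality audit; unions count each record once."""
    cfg = config or AuditConfig.default()
    n = dataset.n

    def stat(count: int) -> Stat:
        return Stat(count, None if n == 0 else round1(100.0 * count / n))

    missing_sets = find_missing(dataset, cfg)
    missing_union: set = set().union(*missing_sets.values()) \
        if missing_sets else set()

    variant_stats: dict[str, Stat] = {}
    variant_union: set = set()
    unmapped: dict[str, int] = {}
    for column, amap in cfg.alias_maps.items():
        if column not in dataset.df.columns:
            continue
        scan = find_variant_text(dataset, column, amap, cfg.missing_markers)
        # a record missing this field cannot also be a variant of it
        variant_stats[column] = stat(len(scan.flagged))
        variant_union |= scan.flagged
        if scan.unmapped:
            unmapped[column] = len(scan.unmapped)

    incons_sets = find_inconsistent(dataset, cfg)
    incons_union: set = set().union(*incons_sets.values())

    any_error = missing_union | variant_union | incons_union
    error_free = n - len(any_error)
    recorders = _recorder_count(dataset, cfg)
    per_person = (None if recorders == 0
                  else round1(error_free / recorders))
    records_pp = (None if recorders == 0 else round1(n / recorders))

    return AuditReport(
        source_label=dataset.source_label,
        total_rows=n,
        recorders=recorders,
        per_field_missing={k: stat(len(v)) for k, v in missing_sets.items()},
        missing_union=stat(len(missing_union)),
        variant_text=variant_stats,
        variant_union=stat(len(variant_union)),
        inconsistent={k: stat(len(v)) for k, v in incons_sets.items()},
        inconsistent_union=stat(len(incons_union)),
        any_error=stat(len(any_error)),
        error_free=stat(error_free),
        error_free_per_person=per_person,
        records_per_person=records_pp,
        unmapped_text=unmapped,
    )


# --------------------------------------------------------------------------
# category statistics


def category_field_stats(dataset: Dataset, registry: Registry,
                         markers: Sequence[str] = DEFAULT_MISSING_MARKERS,
                         ) -> dict[str, dict[str, float]]:
    """Per-category mean and sample sd of filled-field counts per record.

    For each record, counts the non-missing cells among the registry
    variables tagged with the record's category.  Single-record categories
    report sd 0.0 by convention.
    """
    if "record_category" not in dataset.df.columns:
        raise KeyError("dataset lacks a record_category column")
    out: dict[str, dict[str, float]] = {}
    for category in CATEGORIES:
        variables = [v for v in registry.category_variables(category)
                     if v in dataset.df.columns]
        rows = dataset.df[dataset.df["record_category"] == category]
        if rows.empty:
            continue
        filled = pd.Series(0, index=rows.index)
        for col in variables:
            filled += ~_missing_mask(rows[col], rows.index, markers)
        mean = float(filled.mean())
        sd = 0.0 if len(filled) < 2 else float(filled.std(ddof=1))
        out[category] = {"mean": mean, "sd": sd, "n_records": len(filled)}
    return out


def category_record_counts(dataset: Dataset) -> pd.DataFrame:
    """Contingency of record counts, categories x recorders, with a mean
    and sample-sd column across recorders."""
    if dataset.n == 0:
        return pd.DataFrame(0, index=list(RECORD_CATEGORIES),
                            columns=["mean", "sd"])
    tab = pd.crosstab(dataset.df["record_category"], dataset.df["recorder"])
    tab = tab.reindex(list(RECORD_CATEGORIES), fill_value=0)
    counts = tab.astype(float)
    tab["mean"] = counts.mean(axis=1)
    tab["sd"] = counts.std(axis=1, ddof=1).fillna(0.0) \
        if counts.shape[1] > 1 else 0.0
    return tab


def suggest_aliases(values: Iterable[str], canonicals: Iterable[str],
                    cutoff: float = 0.75) -> dict[str, str]:
    """Edit-distance suggestions mapping unmapped values to canonical
    names.  Advisory only — never applied automatically."""
    canon = list(canonicals)
    out: dict[str, str] = {}
    for v in values:
        hits = difflib.get_close_matches(_norm(v), [_norm(c) for c in canon],
                                         n=1, cutoff=cutoff)
        if hits:
            out[v] = canon[[_norm(c) for c in canon].index(hits[0])]
    return out
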