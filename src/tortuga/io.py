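"""Readers and writers: flat CSV exports, messy paper-forms CSV dialects
and JSON session files.

The flat export is the interchange surface: one row per record, one
column per logical variable in registry order after the bookkeeping
columns, UTF-8, RFC-4180 quoting.  Cells are kept as text end to end —
numeric interpretation happens at audit time — so a write/read round trip
is the identity and nothing a quality audit needs as evidence (variant
spellings, blank markers) is ever normalized away on load.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from datetime import datetime
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .audit import BOOKKEEPING_COLUMNS, Dataset
from .records import (Coordinates, CrawlRecord, ExcavationRecord, NestRecord,
                      RelocationRecord, Session, TurtleRecord, WeatherBlock,
                      replicate_weather)
from .registry import Registry

__all__ = [
    "Dialect",
    "write_flat_csv",
    "read_flat_csv",
    "read_paperforms_csv",
    "flag_unparseable",
    "write_session_json",
    "read_session_json",
    "session_to_dataset",
]


# --------------------------------------------------------------------------
# flat CSV


def _ordered_columns(df_columns: Sequence[str],
                     registry: Optional[Registry]) -> list[str]:
    cols = list(df_columns)
    if registry is None:
        return cols
    order = list(BOOKKEEPING_COLUMNS) + registry.variable_ids
    known = [c for c in order if c in cols]
    rest = [c for c in cols if c not in known]
    return known + rest


def write_flat_csv(dataset: Dataset, path: str | Path,
                   registry: Optional[Registry] = None) -> Path:
    """Write one row per record; header always present (empty dataset
    yields a header-only file)."""
    path = Path(path)
    cols = _ordered_columns(dataset.df.columns, registry)
    dataset.df[cols].to_csv(path, index=False, encoding="utf-8",
                            quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
    return path


def _read_header(path: Path) -> list[str]:
    with path.open(newline="", encoding="utf-8") as fh:
        try:
            header = next(csv.reader(fh))
        except StopIteration:
            raise ValueError(f"{path}: missing header row") from None
    dupes = {h for h in header if header.count(h) > 1}
    if dupes:
        raise ValueError(f"{path}: duplicate headers {sorted(dupes)}")
    return header


def read_flat_csv(path: str | Path,
                  registry: Optional[Registry] = None) -> Dataset:
    """Read a flat export; columns unknown to the registry are preserved
    in the dataset's ``extra_columns`` side channel, never dropped."""
    path = Path(path)
    _read_header(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False,
                     encoding="utf-8")
    extra: dict[str, list] = {}
    if registry is not None:
        known = set(BOOKKEEPING_COLUMNS) | set(registry.variable_ids)
        for col in [c for c in df.columns if c not in known]:
            extra[col] = df[col].tolist()
            df = df.drop(columns=[col])
    return Dataset(df=df, source_label=path.stem, extra_columns=extra)


# --------------------------------------------------------------------------
# paper-forms dialect


@dataclass
class Dialect:
    """How a hand-typed spreadsheet deviates from the flat export: header
    spellings, blank markers, decimal separator and date formats."""

    header_aliases: dict[str, str] = dc_field(default_factory=dict)
    missing_markers: tuple[str, ...] = ("", "-", "?", "NA", "N/A")
    decimal_separator: str = "."
    date_formats: tuple[str, ...] = ("%Y-%m-%d", "%d/%m/%Y", "%d-%m-%Y")

    @classmethod
    def from_file(cls, path: str | Path) -> "Dialect":
        doc = json.loads(Path(path).read_text())
        return cls(
            header_aliases=dict(doc.get("header_aliases", {})),
            missing_markers=tuple(doc.get("missing_markers",
                                          cls.missing_markers)),
            decimal_separator=doc.get("decimal_separator", "."),
            date_formats=tuple(doc.get("date_formats", cls.date_formats)),
        )

    def validate_against(self, registry: Registry) -> None:
        known = set(registry.variable_ids) | set(BOOKKEEPING_COLUMNS)
        bad = [t for t in self.header_aliases.values() if t not in known]
        if bad:
            raise ValueError(f"dialect aliases target unknown variables: "
                             f"{sorted(set(bad))}")


def read_paperforms_csv(path: str | Path, dialect: Dialect,
                        registry: Optional[Registry] = None) -> Dataset:
    """Read a paper-forms-dialect CSV.

    Headers are remapped through the dialect aliases; blank markers are
    normalized to empty cells in the working table; dates are normalized
    to ISO; the decimal separator is fixed on numeric columns.  The
    untouched original table is kept in ``raw`` so variant-text evidence
    survives, and headers mapping to no known variable go to the
    ``extra_columns`` side channel with a warning entry.
    """
    path = Path(path)
    if registry is not None:
        dialect.validate_against(registry)
    _read_header(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False,
                      encoding="utf-8")
    df = raw.rename(columns=dialect.header_aliases)

    extra: dict[str, list] = {}
    if registry is not None:
        known = set(BOOKKEEPING_COLUMNS) | set(registry.variable_ids)
        for col in [c for c in df.columns if c not in known]:
            extra[col] = df[col].tolist()
            df = df.drop(columns=[col])
        extra_warn = sorted(extra)
        if extra_warn:
            extra["_warnings"] = [
                f"unmapped header {c!r} kept in side channel"
                for c in extra_warn
            ]

    marks = {m.strip().casefold() for m in dialect.missing_markers}
    df = df.map(lambda c: "" if str(c).strip().casefold() in marks
                else str(c))

    number_cols = set()
    if registry is not None:
        number_cols = {fd.variable_id for fd in registry
                       if fd.entry_type == "number"}
    if dialect.decimal_separator != ".":
        for col in df.columns:
            if col in number_cols:
                df[col] = df[col].str.replace(dialect.decimal_separator, ".",
                                              regex=False)
    if "record_date" in df.columns:
        df["record_date"] = df["record_date"].map(
            lambda c: _normalize_date(c, dialect.date_formats))
    return Dataset(df=df, source_label=path.stem, extra_columns=extra,
                   raw=raw)


def _normalize_date(cell: str, formats: Sequence[str]) -> str:
    text = str(cell).strip()
    if not text:
        return ""
    for fmt in formats:
        try:
            return datetime.strptime(text, fmt).date().isoformat()
        except ValueError:
            continue
    return text  # unparseable: preserved, flagged downstream


def flag_unparseable(dataset: Dataset,
                     registry: Registry) -> dict[str, list]:
    """Ids of non-empty cells in number-typed columns that do not parse
    as numbers.  Cells are flagged, never dropped."""
    out: dict[str, list] = {}
    number_cols = {fd.variable_id for fd in registry
                   if fd.entry_type == "number"}
    for col in dataset.df.columns:
        if col not in number_cols:
            continue
        bad = []
        for idx, cell in dataset.df[col].items():
            text = str(cell).strip()
            if not text:
                continue
            try:
                float(text)
            except ValueError:
                bad.append(idx)
        if bad:
            out[col] = bad
    return out


# --------------------------------------------------------------------------
# session files


_RECORD_TYPES = {cls.kind: cls for cls in
                 (TurtleRecord, NestRecord, RelocationRecord,
                  ExcavationRecord, CrawlRecord)}


def _record_to_dict(rec) -> dict:
    d = dataclasses.asdict(rec)
    d["kind"] = rec.kind
    return d


def _record_from_dict(d: Mapping):
    d = dict(d)
    cls = _RECORD_TYPES[d.pop("kind")]
    for key in ("location", "new_location"):
        if d.get(key) is not None:
            d[key] = Coordinates(**d[key])
    if cls is TurtleRecord:  # triplicate measurements are tuples
        for key in ("ccl_cm", "ccw_cm", "track_width_cm"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
    return cls(**d)


def write_session_json(session: Session, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "user": session.user,
        "beach": session.beach,
        "start_time": session.start_time.isoformat(),
        "strict": session.strict,
        "weather": [
            {**{k: v for k, v in dataclasses.asdict(b).items()
                if k != "recorded_at"},
             "recorded_at": (b.recorded_at.isoformat()
                             if b.recorded_at else None)}
            for b in session.weather_history
        ],
        "records": [_record_to_dict(r) for r in session.records],
        "issued_tags": sorted(session.issued_tags),
    }
    path.write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")
    return path


def read_session_json(path: str | Path,
                      clock=datetime.now) -> Session:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    session = Session(
        user=doc["user"],
        beach=doc["beach"],
        start_time=datetime.fromisoformat(doc["start_time"]),
        clock=clock,
        strict=bool(doc.get("strict", True)),
    )
    for b in doc.get("weather", []):
        b = dict(b)
        at = b.pop("recorded_at", None)
        session.weather_history.append(WeatherBlock(
            **b, recorded_at=datetime.fromisoformat(at) if at else None))
    session.records = [_record_from_dict(d) for d in doc.get("records", [])]
    session.issued_tags = set(doc.get("issued_tags", []))
    return session


_WEATHER_VARS = ("tide_level", "moon_phase", "cloud_cover",
                 "artificial_light", "human_disturbance")


def session_to_dataset(session: Session, registry: Registry) -> Dataset:
    """Flatten a session into the export table, replicating the night's
    weather onto every record."""
    rows = []
    pairs = (replicate_weather(session) if session.weather_history
             else [(r, None) for r in session.records])
    for i, (rec, weather) in enumerate(pairs):
        row = {c: "" for c in
               list(BOOKKEEPING_COLUMNS) + registry.variable_ids}
        row.update({
            "record_id": f"{session.user}-{i + 1:04d}",
            "record_category": rec.category,
            "recorder": session.user,
            "user_name": session.user,
            "beach_name": session.beach,
            "save_action": "Save",
        })
        if weather is not None:
            for var in _WEATHER_VARS:
                row[var] = getattr(weather, var, "") or ""
        for var, val in rec.to_fields().items():
            if var in row:
                row[var] = val
        rows.append(row)
    cols = list(BOOKKEEPING_COLUMNS) + registry.variable_ids
    df = pd.DataFrame(rows, columns=cols, dtype="string") if rows else \
        pd.DataFrame(columns=cols, dtype="string")
    return Dataset(df=df, source_label=f"session-{session.user}")
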