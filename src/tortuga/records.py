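"""Typed survey records and the in-entry safeguards.

The entry software prevents three error classes at the moment of recording:
missing relevant fields (mandatory gating and auto-filled date/time), free
text drifting into variant spellings (choice lists and auto-generated nest
tags) and inconsistent values (egg-partition and coordinate-range checks).
This module is the headless equivalent: records are dataclasses, a
:class:`Session` refuses to save a record that would violate a safeguard,
and the excavation success rates are computed exactly as the entry software
does.

Every auto-fill uses an injectable clock so behaviour is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from datetime import datetime
from typing import Callable, Iterable, Mapping, Optional, Sequence

from . import _geo
from .registry import Registry, mandatory_fields

__all__ = [
    "SPECIES",
    "RecordValidationError",
    "WeatherNotSetError",
    "MissingMandatoryError",
    "UnknownNestTagError",
    "DuplicateNestTagError",
    "WeatherBlock",
    "Coordinates",
    "RegionBounds",
    "TurtleRecord",
    "NestRecord",
    "RelocationRecord",
    "ExcavationRecord",
    "CrawlRecord",
    "Session",
    "SeasonStore",
    "open_session",
    "generate_nest_tag",
    "add_record",
    "replicate_weather",
    "check_egg_partition",
    "check_coordinates",
    "hatch_success",
    "emergence_success",
]

#: The six species the entry software supports.
SPECIES = (
    "Dermochelys coriacea",
    "Eretmochelys imbricata",
    "Chelonia mydas",
    "Caretta caretta",
    "Lepidochelys kempii",
    "Lepidochelys olivacea",
)

#: Default beach codes used when auto-generating nest tags.
BEACH_CODES = ("HMB", "AKB", "JDB", "SAK")


class RecordValidationError(ValueError):
    """A record failed an in-entry safeguard."""


class WeatherNotSetError(RecordValidationError):
    pass


class MissingMandatoryError(RecordValidationError):
    def __init__(self, field_ids: Sequence[str]):
        self.field_ids = list(field_ids)
        super().__init__(f"missing mandatory fields: {', '.join(field_ids)}")


class UnknownNestTagError(RecordValidationError):
    pass


class DuplicateNestTagError(RecordValidationError):
    pass


# --------------------------------------------------------------------------
# value types


@dataclass
class WeatherBlock:
    """Night-level conditions, replicated onto each record of the night."""

    tide_level: str
    moon_phase: str
    cloud_cover: str
    artificial_light: str = ""
    human_disturbance: str = ""
    recorded_at: Optional[datetime] = None


@dataclass
class Coordinates:
    """A position either in decimal degrees or as a UTM grid reference."""

    system: str = "decimal_degrees"  # or "UTM"
    lat: Optional[float] = None
    lon: Optional[float] = None
    easting: Optional[float] = None
    northing: Optional[float] = None
    zone: str = ""

    def __post_init__(self) -> None:
        if self.system not in ("decimal_degrees", "UTM"):
            raise ValueError(f"unknown coordinate system {self.system!r}")
        if self.system == "UTM":
            if not self.zone:
                raise ValueError("UTM coordinates require a zone designator")
            vals = (self.easting, self.northing)
        else:
            vals = (self.lat, self.lon)
        import math

        for v in vals:
            if v is None or not math.isfinite(float(v)):
                raise ValueError("coordinate values must be finite numbers")

    def to_decimal(self) -> tuple[float, float]:
        """(lat, lon) in decimal degrees, converting from UTM if needed."""
        if self.system == "decimal_degrees":
            return float(self.lat), float(self.lon)
        num, northern = _geo.parse_zone(self.zone)
        return _geo.utm_to_latlon(float(self.easting), float(self.northing),
                                  num, northern)


@dataclass(frozen=True)
class RegionBounds:
    """Closed bounding box for the coordinate-range check, in degrees."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def __post_init__(self) -> None:
        if not (self.lat_min < self.lat_max and self.lon_min < self.lon_max):
            raise ValueError("bounds require min < max on both axes")

    def contains(self, lat: float, lon: float) -> bool:
        return (self.lat_min <= lat <= self.lat_max
                and self.lon_min <= lon <= self.lon_max)


#: Default regional box around the Akumal beaches (WGS84 degrees).
AKUMAL_BOUNDS = RegionBounds(20.33, 20.43, -87.40, -87.20)


# --------------------------------------------------------------------------
# record types


def _stringify(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "yes" if value else "no"
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


@dataclass
class TurtleRecord:
    kind = "TURTLE"
    category = "TURTLE_SEEN"
    windows = ("4.1.1", "4.1.2", "4.1.3", "4.1.4", "4.1.5")

    species: str = ""
    old_tag_number: str = ""
    new_tag_number: str = ""
    ccl_cm: tuple[float, ...] = ()
    ccw_cm: tuple[float, ...] = ()
    track_width_cm: tuple[float, ...] = ()
    ptl_cm: Optional[float] = None
    ttl_cm: Optional[float] = None
    head_length_cm: Optional[float] = None
    head_width_cm: Optional[float] = None
    weight_kg: Optional[float] = None
    activity: str = ""
    health_condition: str = ""
    status_after: str = ""
    distinctive_marks: str = ""
    notes: str = ""
    date: str = ""
    time: str = ""

    def __post_init__(self) -> None:
        if self.species and self.species not in SPECIES:
            raise RecordValidationError(f"unknown species {self.species!r}")
        for name in ("ccl_cm", "ccw_cm", "track_width_cm"):
            for v in getattr(self, name):
                if v <= 0:
                    raise RecordValidationError(f"{name} must be positive")
        for name in ("ptl_cm", "ttl_cm", "head_length_cm", "head_width_cm",
                     "weight_kg"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise RecordValidationError(f"{name} must be positive")

    def to_fields(self) -> dict[str, str]:
        def mean(xs):
            return sum(xs) / len(xs) if xs else None

        return _drop_blank({
            "species": self.species,
            "old_tag_number": self.old_tag_number,
            "new_tag_number": self.new_tag_number,
            "ccl_cm": mean(self.ccl_cm),
            "ccw_cm": mean(self.ccw_cm),
            "turtle_track_width_cm": mean(self.track_width_cm),
            "ptl_cm": self.ptl_cm,
            "ttl_cm": self.ttl_cm,
            "head_length_cm": self.head_length_cm,
            "head_width_cm": self.head_width_cm,
            "weight_kg": self.weight_kg,
            "activity": self.activity,
            "health_condition": self.health_condition,
            "status_after": self.status_after,
            "distinctive_marks": self.distinctive_marks,
            "turtle_notes": self.notes,
            "record_date": self.date,
            "record_time": self.time,
        })


@dataclass
class NestRecord:
    kind = "NEST_PRE"
    category = "NEST_SEEN"
    windows = ("4.2.1", "4.2.2", "4.2.3", "4.2.4", "4.2.5", "4.2.6",
               "4.2.7", "4.2.8")

    nest_tag: str = ""
    beach: str = ""
    sector: str = ""
    references: str = ""
    location: Optional[Coordinates] = None
    mark_type: str = ""
    female_present: Optional[bool] = None
    female_tag_number: str = ""
    total_eggs: Optional[int] = None
    clutch_complete: Optional[bool] = None
    n_incubated: Optional[int] = None
    n_yolkless: Optional[int] = None
    n_multiyolked: Optional[int] = None
    deposition_time: str = ""
    sand_temp_c: Optional[float] = None
    sand_humidity_pct: Optional[float] = None
    beach_position: str = ""
    distance_high_tide_m: Optional[float] = None
    depth_top_cm: Optional[float] = None
    depth_bottom_cm: Optional[float] = None
    vegetation_type: str = ""
    dune_height_m: Optional[float] = None
    date: str = ""
    time: str = ""

    def __post_init__(self) -> None:
        for name in ("total_eggs", "n_incubated", "n_yolkless",
                     "n_multiyolked"):
            v = getattr(self, name)
            if v is not None and (int(v) != v or v < 0):
                raise RecordValidationError(
                    f"{name} must be a non-negative integer"
                )

    def to_fields(self) -> dict[str, str]:
        lat = lon = None
        if self.location is not None:
            lat, lon = self.location.to_decimal()
        return _drop_blank({
            "nest_tag": self.nest_tag,
            "nest_beach_name": self.beach,
            "nest_sector_number": self.sector,
            "nest_references": self.references,
            "nest_latitude": lat,
            "nest_longitude": lon,
            "nest_mark_type": self.mark_type,
            "female_present": self.female_present,
            "female_tag_number": self.female_tag_number,
            "total_eggs": self.total_eggs,
            "clutch_complete": self.clutch_complete,
            "n_incubated": self.n_incubated,
            "n_yolkless": self.n_yolkless,
            "n_multiyolked": self.n_multiyolked,
            "deposition_time": self.deposition_time,
            "sand_temp_c": self.sand_temp_c,
            "sand_humidity_pct": self.sand_humidity_pct,
            "beach_position": self.beach_position,
            "distance_high_tide_m": self.distance_high_tide_m,
            "depth_top_cm": self.depth_top_cm,
            "depth_bottom_cm": self.depth_bottom_cm,
            "vegetation_type": self.vegetation_type,
            "dune_height_m": self.dune_height_m,
            "record_date": self.date,
            "record_time": self.time,
        })


@dataclass
class RelocationRecord:
    kind = "NEST_MOVED"
    category = "NEST_MOVED"
    windows = ("4.3.1", "4.3.2")

    nest_tag: str = ""
    new_location: Optional[Coordinates] = None
    date: str = ""
    time: str = ""

    def to_fields(self) -> dict[str, str]:
        lat = lon = None
        if self.new_location is not None:
            lat, lon = self.new_location.to_decimal()
        return _drop_blank({
            "nest_tag": self.nest_tag,
            "nest_latitude": lat,
            "nest_longitude": lon,
            "record_date": self.date,
            "record_time": self.time,
        })


@dataclass
class ExcavationRecord:
    kind = "NEST_POST"
    category = "NEST_EXCAVATED"
    windows = ("4.4.1", "4.4.2", "4.4.3")

    nest_tag: str = ""
    species: str = ""
    hatch_date: str = ""
    emergence_time: str = ""
    n_emerged: Optional[int] = None
    n_live_in_nest: int = 0
    n_undeveloped: int = 0
    n_unhatched: int = 0
    n_shells: int = 0
    n_dead_hatchlings: int = 0
    n_predated: int = 0
    genetic_sample_codes: str = ""
    fate: str = ""
    conclusion_date: str = ""
    date: str = ""
    time: str = ""

    _COUNTS = ("n_live_in_nest", "n_undeveloped", "n_unhatched", "n_shells",
               "n_dead_hatchlings", "n_predated")

    def __post_init__(self) -> None:
        for name in self._COUNTS:
            if getattr(self, name) < 0:
                raise RecordValidationError(f"{name} must be non-negative")
        if self.fate and self.fate not in (
                "flooded", "invaded by predators", "dislocated", "other"):
            raise RecordValidationError(f"unknown nest fate {self.fate!r}")

    def to_fields(self) -> dict[str, str]:
        return _drop_blank({
            "nest_tag": self.nest_tag,
            "species": self.species,
            "hatch_date": self.hatch_date,
            "emergence_time": self.emergence_time,
            "n_emerged": self.n_emerged,
            "n_live_in_nest": self.n_live_in_nest,
            "n_undeveloped": self.n_undeveloped,
            "n_unhatched": self.n_unhatched,
            "n_shells": self.n_shells,
            "n_dead_hatchlings": self.n_dead_hatchlings,
            "n_predated": self.n_predated,
            "genetic_sample_codes": self.genetic_sample_codes,
            "nest_fate": self.fate,
            "conclusion_date": self.conclusion_date,
            "record_date": self.date,
            "record_time": self.time,
        })


@dataclass
class CrawlRecord:
    kind = "CRAWL"
    category = "CRAWL_ANY"
    windows = ("4.5.1",)

    track_type: str = ""
    track_width_cm: Optional[float] = None
    nest_deposition: Optional[bool] = None
    false_crawl_reason: str = ""
    date: str = ""
    time: str = ""

    def __post_init__(self) -> None:
        if self.track_type and self.track_type not in (
                "green", "loggerhead", "hawksbill", "other"):
            raise RecordValidationError(
                f"unknown track type {self.track_type!r}"
            )

    def to_fields(self) -> dict[str, str]:
        dep = None
        if self.nest_deposition is not None:
            dep = "Y" if self.nest_deposition else "N"
        return _drop_blank({
            "track_type": self.track_type,
            "crawl_track_width_cm": self.track_width_cm,
            "nest_deposition": dep,
            "false_crawl_reason": self.false_crawl_reason,
            "record_date": self.date,
            "record_time": self.time,
        })


AnyRecord = (TurtleRecord, NestRecord, RelocationRecord, ExcavationRecord,
             CrawlRecord)


def _drop_blank(d: Mapping[str, object]) -> dict[str, str]:
    return {k: _stringify(v) for k, v in d.items()
            if v is not None and _stringify(v) != ""}


# --------------------------------------------------------------------------
# session and safeguards


@dataclass
class SeasonStore:
    """Season-wide nest-tag store shared across sessions: per-beach tag
    counters plus the set of every tag issued or registered so far."""

    tags: set[str] = dc_field(default_factory=set)
    counters: dict[str, int] = dc_field(default_factory=dict)

    def register(self, tag: str) -> None:
        self.tags.add(tag)


@dataclass
class Session:
    """One night of recording by one user on one beach."""

    user: str
    beach: str
    start_time: datetime
    clock: Callable[[], datetime]
    strict: bool = True
    weather_history: list[WeatherBlock] = dc_field(default_factory=list)
    records: list = dc_field(default_factory=list)
    issued_tags: set[str] = dc_field(default_factory=set)
    season_store: Optional[SeasonStore] = None

    @property
    def weather(self) -> Optional[WeatherBlock]:
        return self.weather_history[-1] if self.weather_history else None

    def set_weather(self, block: WeatherBlock) -> None:
        if block.recorded_at is None:
            block.recorded_at = self.clock()
        self.weather_history.append(block)

    def known_tags(self) -> set[str]:
        tags = set(self.issued_tags)
        if self.season_store is not None:
            tags |= self.season_store.tags
        return tags


def open_session(user: str, beach: str,
                 clock: Callable[[], datetime] = datetime.now, *,
                 strict: bool = True,
                 season_store: Optional[SeasonStore] = None) -> Session:
    """Open a recording session; start time is auto-filled from *clock*."""
    if not user.strip():
        raise MissingMandatoryError(["user_name"])
    if not beach.strip():
        raise MissingMandatoryError(["beach_name"])
    return Session(user=user, beach=beach, start_time=clock(), clock=clock,
                   strict=strict, season_store=season_store)


def generate_nest_tag(session: Session, beach_code: str,
                      season_store: Optional[SeasonStore] = None) -> str:
    """Issue the next free tag ``{BEACH_CODE}-{NNN}`` for *beach_code*.

    The sequence number always advances past any tag already registered
    (auto-issued or entered manually), so a tag is never issued twice.
    """
    store = season_store or session.season_store or SeasonStore()
    if session.season_store is None and season_store is None:
        session.season_store = store
    if not beach_code.strip():
        raise RecordValidationError("empty beach code")
    taken = store.tags | session.issued_tags
    seq = store.counters.get(beach_code, 0) + 1
    while f"{beach_code}-{seq:03d}" in taken:
        seq += 1
    tag = f"{beach_code}-{seq:03d}"
    store.counters[beach_code] = seq
    store.register(tag)
    session.issued_tags.add(tag)  # reserved for this session's nest record
    return tag


def _autofill_timestamps(session: Session, record) -> None:
    now = session.clock()
    if not record.date:
        record.date = now.date().isoformat()
    if not record.time:
        record.time = now.strftime("%H:%M")


def _missing_mandatory(record, registry: Registry) -> list[str]:
    fields = record.to_fields()
    missing: list[str] = []
    for window in record.windows:
        try:
            window_fields = mandatory_fields(registry, window)
        except KeyError:
            continue
        for fd in window_fields:
            if not fields.get(fd.variable_id, "").strip():
                missing.append(fd.field_id)
    return missing


def add_record(session: Session, record, registry: Registry):
    """Validate and append *record*; raises instead of saving bad data.

    Checks, in order: the weather gate (strict sessions), timestamp
    auto-fill, mandatory fields of the record's windows, nest-tag
    resolution for relocations/excavations, and nest-tag uniqueness for
    new nests.
    """
    if not isinstance(record, AnyRecord):
        raise TypeError(f"not a survey record: {type(record).__name__}")
    if session.strict and not session.weather_history:
        raise WeatherNotSetError(
            "weather must be recorded before any record is saved"
        )
    _autofill_timestamps(session, record)
    missing = _missing_mandatory(record, registry)
    if missing:
        raise MissingMandatoryError(missing)
    if isinstance(record, (RelocationRecord, ExcavationRecord)):
        if record.nest_tag not in session.known_tags():
            raise UnknownNestTagError(
                f"nest tag {record.nest_tag!r} does not resolve to a saved "
                "nest"
            )
    if isinstance(record, NestRecord):
        if record.nest_tag in {r.nest_tag for r in session.records
                               if isinstance(r, NestRecord)}:
            raise DuplicateNestTagError(
                f"nest tag {record.nest_tag!r} already used in this session"
            )
        if (session.season_store is not None
                and record.nest_tag in session.season_store.tags
                and record.nest_tag not in session.issued_tags):
            raise DuplicateNestTagError(
                f"nest tag {record.nest_tag!r} already used this season"
            )
        session.issued_tags.add(record.nest_tag)
        if session.season_store is not None:
            session.season_store.register(record.nest_tag)
    session.records.append(record)
    return session


def replicate_weather(session: Session, night_records: Iterable | None = None):
    """Attach to each record the latest weather block recorded at or before
    its timestamp (records earlier than every block get the first block)."""
    if not session.weather_history:
        raise WeatherNotSetError("no weather block recorded for this night")
    records = list(night_records) if night_records is not None \
        else session.records
    blocks = sorted(session.weather_history,
                    key=lambda b: b.recorded_at or session.start_time)
    out = []
    for rec in records:
        stamp = f"{rec.date}T{rec.time}" if rec.date and rec.time else ""
        chosen = blocks[0]
        for b in blocks:
            bt = (b.recorded_at or session.start_time).strftime(
                "%Y-%m-%dT%H:%M")
            if not stamp or bt <= stamp:
                chosen = b
        out.append((rec, chosen))
    return out


# --------------------------------------------------------------------------
# consistency checks and success rates


def check_egg_partition(total_eggs, n_incubated, n_yolkless, n_multiyolked,
                        clutch_complete) -> str:
    """Egg-partition identity check.

    ``consistent`` iff the clutch is complete and total equals the sum of
    the partial counts; ``not_applicable`` when the clutch is partial or
    any count is absent.
    """
    counts = (total_eggs, n_incubated, n_yolkless, n_multiyolked)
    for v in counts:
        if v is not None and (int(v) != v or v < 0):
            raise ValueError("egg counts must be non-negative integers")
    if not clutch_complete or any(v is None for v in counts):
        return "not_applicable"
    total = int(total_eggs)
    return ("consistent"
            if total == int(n_incubated) + int(n_yolkless) + int(n_multiyolked)
            else "mismatch")


def check_coordinates(coord: Coordinates,
                      bounds: RegionBounds = AKUMAL_BOUNDS) -> str:
    """``in_range`` iff *coord* lies inside the closed bounding box."""
    lat, lon = coord.to_decimal()
    return "in_range" if bounds.contains(lat, lon) else "out_of_range"


def _excavation_denominator(exc: ExcavationRecord) -> int:
    return exc.n_shells + exc.n_undeveloped + exc.n_unhatched + exc.n_predated


def hatch_success(exc: ExcavationRecord) -> float:
    """Hatching success: shells over the reconstructed clutch, in percent.

    The denominator is shells + undeveloped + unhatched + predated, the
    standard excavation-inventory reconstruction of clutch size.
    """
    denom = _excavation_denominator(exc)
    if denom <= 0:
        raise ValueError("hatching success undefined: empty excavation "
                         "inventory")
    return 100.0 * exc.n_shells / denom


def emergence_success(exc: ExcavationRecord) -> float:
    """Emergence success: hatchlings that left the nest over the clutch.

    Numerator = shells - live in nest - dead in nest; same denominator as
    :func:`hatch_success`, hence emergence <= hatching always.
    """
    denom = _excavation_denominator(exc)
    if denom <= 0:
        raise ValueError("emergence success undefined: empty excavation "
                         "inventory")
    stayed = exc.n_live_in_nest + exc.n_dead_hatchlings
    if stayed > exc.n_shells:
        raise ValueError("live + dead hatchlings exceed hatched shells")
    return 100.0 * (exc.n_shells - stayed) / denom
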