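"""Field census of the survey-entry software.

The entry software presents its variables through a fixed set of windows
(login, beach details, weather, a record-type menu, five record branches and
a save window).  Every entry field has a window, an entry type (button,
checkbox, drop box, list box, auto-filled, typed number or typed text), an
optional unit and choice list, a mandatory flag and the analysis categories
it belongs to.  Several fields can feed one logical *variable* — e.g. the
curved-carapace measurements are entered three times each — so the census
distinguishes 116 entry fields from 104 variables.

The canonical census ships with the package as ``data/registry.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "ENTRY_TYPES",
    "CATEGORIES",
    "WINDOW_IDS",
    "FieldDef",
    "Registry",
    "RegistryError",
    "load_registry",
    "type_counts",
    "type_share_percent",
    "mandatory_fields",
    "BUNDLED_CENSUS",
]

#: The seven entry types offered by the software.
ENTRY_TYPES = (
    "multiple_buttons",
    "checkbox",
    "drop_box",
    "list_box",
    "autofill",
    "number",
    "text",
)

#: Entry types answered by selection rather than typing.
CHOICE_TYPES = ("multiple_buttons", "checkbox", "drop_box", "list_box")

#: Analysis categories used to group fields for per-record completeness.
CATEGORIES = ("CRAWL_ANY", "TURTLE_SEEN", "NEST_SEEN", "NEST_MOVED")

#: Valid window identifiers, in presentation order.
WINDOW_IDS = (
    "1", "2", "3", "4",
    "4.1.1", "4.1.2", "4.1.3", "4.1.4", "4.1.5",
    "4.2.1", "4.2.2", "4.2.3", "4.2.4", "4.2.5", "4.2.6", "4.2.7", "4.2.8",
    "4.3.1", "4.3.2",
    "4.4.1", "4.4.2", "4.4.3",
    "4.5.1",
    "5",
)

#: Expected totals for the bundled census: distinct variables, total fields
#: and fields per entry type.
BUNDLED_CENSUS = {
    "n_variables": 104,
    "n_fields": 116,
    "type_counts": {
        "multiple_buttons": 4,
        "checkbox": 11,
        "drop_box": 25,
        "list_box": 2,
        "autofill": 6,
        "number": 46,
        "text": 22,
    },
}


class RegistryError(ValueError):
    """A registry file or definition violates a census invariant."""


@dataclass(frozen=True)
class FieldDef:
    """One entry field of the survey software."""

    field_id: str
    label: str
    window_id: str
    entry_type: str
    variable_id: str
    unit: str = ""
    choices: tuple[str, ...] = ()
    mandatory: bool = False
    categories: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.entry_type not in ENTRY_TYPES:
            raise RegistryError(
                f"field {self.field_id!r}: unknown entry type "
                f"{self.entry_type!r}"
            )
        if self.window_id not in WINDOW_IDS:
            raise RegistryError(
                f"field {self.field_id!r}: unknown window {self.window_id!r}"
            )
        if self.entry_type in CHOICE_TYPES and not self.choices:
            raise RegistryError(
                f"field {self.field_id!r}: choice-typed field has no choices"
            )
        bad = set(self.categories) - set(CATEGORIES)
        if bad:
            raise RegistryError(
                f"field {self.field_id!r}: unknown categories {sorted(bad)}"
            )


@dataclass
class Registry:
    """Ordered collection of :class:`FieldDef` with census helpers."""

    fields: list[FieldDef]
    version: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for fd in self.fields:
            if fd.field_id in seen:
                raise RegistryError(f"duplicate field_id {fd.field_id!r}")
            seen.add(fd.field_id)

    def __len__(self) -> int:
        return len(self.fields)

    def __iter__(self) -> Iterator[FieldDef]:
        return iter(self.fields)

    def field(self, field_id: str) -> FieldDef:
        for fd in self.fields:
            if fd.field_id == field_id:
                return fd
        raise KeyError(field_id)

    @property
    def variable_ids(self) -> list[str]:
        """Distinct variable ids in first-appearance order."""
        out: list[str] = []
        seen: set[str] = set()
        for fd in self.fields:
            if fd.variable_id not in seen:
                seen.add(fd.variable_id)
                out.append(fd.variable_id)
        return out

    @property
    def window_ids(self) -> list[str]:
        return sorted({fd.window_id for fd in self.fields},
                      key=WINDOW_IDS.index)

    def fields_in_window(self, window_id: str) -> list[FieldDef]:
        if window_id not in {fd.window_id for fd in self.fields}:
            raise KeyError(f"window {window_id!r} not present in registry")
        return [fd for fd in self.fields if fd.window_id == window_id]

    def category_variables(self, category: str) -> list[str]:
        """Distinct variable ids tagged with *category*, in registry order."""
        if category not in CATEGORIES:
            raise KeyError(category)
        out: list[str] = []
        for fd in self.fields:
            if category in fd.categories and fd.variable_id not in out:
                out.append(fd.variable_id)
        return out

    def choices_for(self, variable_id: str) -> tuple[str, ...]:
        for fd in self.fields:
            if fd.variable_id == variable_id and fd.choices:
                return fd.choices
        return ()

    def check_census(self, expected: Mapping | None = None) -> None:
        """Verify variable/field totals against *expected* (bundled census
        by default); raise :class:`RegistryError` naming the failing total."""
        exp = dict(expected or BUNDLED_CENSUS)
        nvar = len(self.variable_ids)
        if nvar != exp["n_variables"]:
            raise RegistryError(
                f"census: {nvar} distinct variables, expected "
                f"{exp['n_variables']}"
            )
        if len(self.fields) != exp["n_fields"]:
            raise RegistryError(
                f"census: {len(self.fields)} fields, expected "
                f"{exp['n_fields']}"
            )
        got = type_counts(self)
        if dict(got) != exp["type_counts"]:
            raise RegistryError(
                f"census: entry-type totals {dict(got)} != "
                f"{exp['type_counts']}"
            )


def _default_registry_path() -> Path:
    return Path(resources.files("tortuga").joinpath("data/registry.json"))  # type: ignore[arg-type]


def load_registry(path: str | Path | None = None, *,
                  census: Mapping | None = None) -> Registry:
    """Load a registry file (the bundled census when *path* is omitted).

    The bundled file is verified against :data:`BUNDLED_CENSUS`; a custom
    file is census-checked only when *census* is supplied.
    """
    bundled = path is None
    p = _default_registry_path() if bundled else Path(path)
    try:
        doc = json.loads(p.read_text())
    except json.JSONDecodeError as exc:
        raise RegistryError(f"malformed registry file {p}: {exc}") from exc
    if not isinstance(doc, dict) or "fields" not in doc:
        raise RegistryError(f"registry file {p} lacks a 'fields' list")
    fields = [
        FieldDef(
            field_id=d["field_id"],
            label=d.get("label", d["field_id"]),
            window_id=str(d["window_id"]),
            entry_type=d["entry_type"],
            variable_id=d.get("variable_id", d["field_id"]),
            unit=d.get("unit", ""),
            choices=tuple(d.get("choices", ())),
            mandatory=bool(d.get("mandatory", False)),
            categories=tuple(d.get("categories", ())),
        )
        for d in doc["fields"]
    ]
    reg = Registry(fields=fields, version=str(doc.get("version", "")))
    if bundled or census is not None:
        reg.check_census(census)
    return reg


def type_counts(registry: Registry) -> dict[str, int]:
    """Number of fields per entry type (all seven types always present)."""
    counts = {t: 0 for t in ENTRY_TYPES}
    for fd in registry:
        counts[fd.entry_type] += 1
    return counts


def _round_half_away(x: float) -> int:
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def type_share_percent(registry: Registry, types: Iterable[str]) -> int:
    """Integer percentage of fields whose entry type is in *types*.

    Rounded to the nearest integer, ties away from zero.
    """
    wanted = set(types)
    bad = wanted - set(ENTRY_TYPES)
    if bad:
        raise RegistryError(f"unknown entry types {sorted(bad)}")
    total = len(registry)
    if total == 0:
        raise RegistryError("type_share_percent of an empty registry")
    n = sum(1 for fd in registry if fd.entry_type in wanted)
    return _round_half_away(100.0 * n / total)


def mandatory_fields(registry: Registry, window_id: str) -> list[FieldDef]:
    """Mandatory fields of one window, in registry order."""
    return [fd for fd in registry.fields_in_window(window_id) if fd.mandatory]
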