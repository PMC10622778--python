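"""Service-table data model and I/O.

A :class:`ServiceRecord` describes one mobile overdose response service
(MORS) — a hotline or app that remotely monitors a person using drugs alone
and dispatches an emergency response if they become unresponsive — together
with the number of emergency drug-poisoning/overdose responses it has
recorded.  Some services do not track this figure; their count is carried as
the distinct *unknown* state (``None`` in memory, the literal string
``"unknown"`` on disk) and is excluded from every sum and estimate, never
imputed as zero.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "MODALITIES",
    "COUNTRY_SCOPES",
    "UNKNOWN",
    "SchemaError",
    "ValidationError",
    "UnknownCountError",
    "ServiceRecord",
    "ServiceTable",
    "load_service_table",
    "write_service_table",
    "builtin_table1",
    "known_counts",
]

MODALITIES = frozenset({"hotline", "app", "hybrid"})
COUNTRY_SCOPES = frozenset({"canada", "usa", "both", "global"})

#: On-disk spelling of the unknown-count state.
UNKNOWN = "unknown"

_REQUIRED_COLUMNS = ("name", "modality", "country_scope", "n_events")
_ALL_COLUMNS = (
    "name",
    "modality",
    "jurisdiction",
    "country_scope",
    "period_start",
    "period_end",
    "n_events",
    "source_note",
)


class SchemaError(ValueError):
    """An input table is structurally malformed (e.g. a required column is missing)."""


class ValidationError(ValueError):
    """A record violates a field-level invariant (value, enumeration, uniqueness)."""


class UnknownCountError(ValueError):
    """An operation that needs a numeric count met an unknown one.

    Filter the table with :func:`known_counts` (or
    :meth:`ServiceTable.known_counts`) before estimating.
    """


def _parse_count(value, record_name: str) -> int | None:
    if value is None:
        return None
    if isinstance(value, str):
        text = value.strip()
        if text.lower() in {UNKNOWN, "", "na", "n/a"}:
            return None
        try:
            value = int(text)
        except ValueError:
            raise ValidationError(
                f"record {record_name!r}: n_events {text!r} is neither an "
                f"integer nor {UNKNOWN!r}"
            ) from None
    if isinstance(value, float):
        if not value.is_integer():
            raise ValidationError(
                f"record {record_name!r}: n_events must be an integer, got {value!r}"
            )
        value = int(value)
    if not isinstance(value, int):
        raise ValidationError(
            f"record {record_name!r}: n_events must be an integer, got {value!r}"
        )
    if value < 0:
        raise ValidationError(
            f"record {record_name!r}: n_events must be non-negative, got {value}"
        )
    return value


@dataclass(frozen=True)
class ServiceRecord:
    """One MORS and its observed emergency-response count.

    ``n_events`` is ``None`` when the service does not report the figure.
    ``period_start``/``period_end`` are calendar months (``YYYY-MM``) or
    ``"unknown"``; the observation period is metadata only and enters no
    computation.
    """

    name: str
    modality: str
    country_scope: str
    n_events: int | None
    jurisdiction: str = ""
    period_start: str = UNKNOWN
    period_end: str = UNKNOWN
    source_note: str = ""

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise ValidationError("service name must be non-empty")
        if self.modality not in MODALITIES:
            raise ValidationError(
                f"record {self.name!r}: modality {self.modality!r} not in "
                f"{sorted(MODALITIES)}"
            )
        if self.country_scope not in COUNTRY_SCOPES:
            raise ValidationError(
                f"record {self.name!r}: country_scope {self.country_scope!r} "
                f"not in {sorted(COUNTRY_SCOPES)}"
            )
        object.__setattr__(self, "n_events", _parse_count(self.n_events, self.name))

    @property
    def count_known(self) -> bool:
        return self.n_events is not None


@dataclass(frozen=True)
class ServiceTable:
    """An ordered collection of uniquely named :class:`ServiceRecord`."""

    records: tuple[ServiceRecord, ...]
    label: str = "service table"

    def __post_init__(self) -> None:
        records = tuple(self.records)
        if not records:
            raise ValidationError("a service table must contain at least one record")
        seen: set[str] = set()
        for rec in records:
            if rec.name in seen:
                raise ValidationError(f"duplicate service name {rec.name!r}")
            seen.add(rec.name)
        object.__setattr__(self, "records", records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def known_counts(
        self, subset: str | Iterable[str] = "all"
    ) -> list[tuple[str, int]]:
        return known_counts(self, subset)

    def total_known(self, subset: str | Iterable[str] = "all") -> int:
        return sum(n for _, n in self.known_counts(subset))

    def n_unknown(self) -> int:
        return sum(1 for rec in self.records if not rec.count_known)

    def subset(self, scopes: Iterable[str], label: str | None = None) -> "ServiceTable":
        scopes = _normalise_subset(scopes)
        kept = tuple(r for r in self.records if r.country_scope in scopes)
        return ServiceTable(kept, label or f"{self.label} [{'/'.join(sorted(scopes))}]")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = {col: getattr(rec, col) for col in _ALL_COLUMNS}
            row["n_events"] = UNKNOWN if rec.n_events is None else rec.n_events
            rows.append(row)
        return pd.DataFrame(rows, columns=list(_ALL_COLUMNS))


def _normalise_subset(subset: str | Iterable[str]) -> frozenset[str]:
    if isinstance(subset, str):
        if subset == "all":
            return COUNTRY_SCOPES
        subset = {subset}
    scopes = frozenset(str(s).lower() for s in subset)
    bad = scopes - COUNTRY_SCOPES
    if bad:
        raise ValidationError(f"unknown country_scope value(s): {sorted(bad)}")
    return scopes


def known_counts(
    table: ServiceTable, subset: str | Iterable[str] = "all"
) -> list[tuple[str, int]]:
    """Known ``(name, count)`` pairs matching a country-scope filter, in table order.

    ``subset`` is ``"all"``, a scope name, or a set of scope names.  A
    Canada-exclusive analysis uses ``{"canada"}``, which drops services
    operating in both countries or globally.
    """
    scopes = _normalise_subset(subset)
    return [
        (rec.name, rec.n_events)
        for rec in table.records
        if rec.count_known and rec.country_scope in scopes
    ]


def _records_from_rows(rows: Sequence[dict], label: str) -> ServiceTable:
    if not rows:
        raise SchemaError("input table has no rows")
    for col in _REQUIRED_COLUMNS:
        if col not in rows[0]:
            raise SchemaError(f"missing required column {col!r}")
    records = []
    for row in rows:
        kwargs = {col: row.get(col) for col in _ALL_COLUMNS if row.get(col) is not None}
        kwargs.setdefault("jurisdiction", "")
        kwargs.setdefault("source_note", "")
        records.append(ServiceRecord(**kwargs))
    return ServiceTable(tuple(records), label=label)


def load_service_table(path: str | Path, format: str | None = None) -> ServiceTable:
    """Read and validate a service table from CSV or JSON.

    CSV: comma-separated, UTF-8, header row required.  JSON: an array of
    objects keyed by field name.  ``format`` defaults to the file suffix.
    Unknown counts are written and read as the string ``"unknown"``.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format not in {"csv", "json"}:
        raise SchemaError(f"unsupported format {format!r} (expected csv or json)")
    if format == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise SchemaError("CSV file is empty (no header row)")
            rows = [dict(r) for r in reader]
            missing = [c for c in _REQUIRED_COLUMNS if c not in reader.fieldnames]
            if missing:
                raise SchemaError(f"missing required column {missing[0]!r}")
    else:
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise SchemaError("JSON service table must be an array of objects")
        rows = data
    return _records_from_rows(rows, label=path.stem)


def write_service_table(
    table: ServiceTable, path: str | Path, format: str | None = None
) -> Path:
    """Write a table as CSV or JSON such that :func:`load_service_table` round-trips."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "csv":
        table.to_frame().to_csv(path, index=False)
    elif format == "json":
        rows = [
            {
                col: (UNKNOWN if col == "n_events" and rec.n_events is None
                      else getattr(rec, col))
                for col in _ALL_COLUMNS
            }
            for rec in table.records
        ]
        path.write_text(json.dumps(rows, indent=1), encoding="utf-8")
    else:
        raise SchemaError(f"unsupported format {format!r} (expected csv or json)")
    return path


def builtin_table1() -> ServiceTable:
    """The packaged eleven-service North American MORS table.

    Nine services report counts (77, 18, 66, 0, 3, 33, 28, 74, 0; sum 299);
    two (iKeepr, The Canary) are unknown.
    """
    ref = resources.files("avert").joinpath("data/table1.csv")
    with resources.as_file(ref) as path:
        table = load_service_table(path, format="csv")
    return replace(table, label="builtin table 1")
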