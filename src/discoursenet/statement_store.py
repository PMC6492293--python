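"""Read, validate, index, and window/stratify coded statement tables.

A *statement* is one coded instance of an actor expressing agreement or
disagreement with a concept in a media article.  Tables arrive as CSV
(RFC-4180, UTF-8, header row) or as a JSON array of objects; both dialects
carry the same eight fields.  Unknown columns are preserved on round-trip but
ignored by analysis.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping

from discoursenet.errors import (
    EmptyCorpusError,
    IntervalError,
    RowError,
    SchemaError,
)

AGREE = "agree"
DISAGREE = "disagree"

#: canonical column order for the CSV dialect
COLUMNS = (
    "statement_id",
    "article_id",
    "source",
    "date",
    "person",
    "organization",
    "actor_type",
    "concept",
    "stance",
)

#: columns that must be present in input files (statement_id may be omitted
#: and is then auto-assigned sequentially)
REQUIRED_COLUMNS = COLUMNS[1:]

_STANCE_ALIASES = {
    "1": AGREE,
    "0": DISAGREE,
    "true": AGREE,
    "false": DISAGREE,
    "agree": AGREE,
    "disagree": DISAGREE,
}

_WS = re.compile(r"\s+")

ActorLevel = Literal["organization", "person"]


def normalize_label(value: str) -> str:
    """Trim and collapse internal whitespace; actor/concept keys are exact
    strings after this normalization (no fuzzy matching)."""
    return _WS.sub(" ", value.strip())


def _parse_stance(raw: str) -> str:
    key = str(raw).strip().lower()
    if key not in _STANCE_ALIASES:
        raise ValueError(f"unrecognized stance value {raw!r}")
    return _STANCE_ALIASES[key]


def _parse_date(raw: str) -> dt.date:
    if isinstance(raw, dt.date):
        return raw
    return dt.date.fromisoformat(str(raw).strip())


@dataclass(frozen=True)
class Statement:
    """One coded utterance: (actor, organization, concept, stance) plus the
    provenance needed for time slicing and per-publication stratification."""

    statement_id: str
    article_id: str
    source: str
    date: dt.date
    person: str
    organization: str
    actor_type: str
    concept: str
    stance: str
    extra: Mapping[str, str] = field(default_factory=dict, compare=True)

    def __post_init__(self) -> None:
        for name in ("person", "organization", "concept"):
            norm = normalize_label(getattr(self, name))
            if not norm:
                raise ValueError(f"{name} is empty after whitespace normalization")
            object.__setattr__(self, name, norm)
        object.__setattr__(self, "source", normalize_label(self.source))
        if self.stance not in (AGREE, DISAGREE):
            raise ValueError(f"stance must be {AGREE!r} or {DISAGREE!r}, got {self.stance!r}")
        if not isinstance(self.date, dt.date):
            raise TypeError("date must be a datetime.date")

    def actor(self, level: ActorLevel) -> str:
        return self.organization if level == "organization" else self.person

    def to_record(self) -> dict[str, str]:
        rec = {
            "statement_id": self.statement_id,
            "article_id": self.article_id,
            "source": self.source,
            "date": self.date.isoformat(),
            "person": self.person,
            "organization": self.organization,
            "actor_type": self.actor_type,
            "concept": self.concept,
            "stance": self.stance,
        }
        rec.update(self.extra)
        return rec


@dataclass(frozen=True)
class Corpus:
    """An ordered collection of statements, optionally restricted to a
    half-open date window [start, end)."""

    statements: tuple[Statement, ...]
    window: tuple[dt.date, dt.date] | None = None

    def __post_init__(self) -> None:
        if self.window is not None:
            start, end = self.window
            if start >= end:
                raise IntervalError(f"window start {start} >= end {end}")
            for s in self.statements:
                if not (start <= s.date < end):
                    raise ValueError(
                        f"statement {s.statement_id} dated {s.date} outside window"
                    )

    def __len__(self) -> int:
        return len(self.statements)

    def __iter__(self):
        return iter(self.statements)

    @property
    def concepts(self) -> tuple[str, ...]:
        return tuple(sorted({s.concept for s in self.statements}))

    @property
    def sources(self) -> tuple[str, ...]:
        return tuple(sorted({s.source for s in self.statements}))

    def actors(self, level: ActorLevel = "organization") -> tuple[str, ...]:
        return tuple(sorted({s.actor(level) for s in self.statements}))

    def actor_index(self, level: ActorLevel = "organization") -> dict[str, tuple[Statement, ...]]:
        """Map each actor key at the chosen level to its statements, in corpus
        order.  Rebuildable from the statements, so always consistent."""
        idx: dict[str, list[Statement]] = defaultdict(list)
        for s in self.statements:
            idx[s.actor(level)].append(s)
        return {a: tuple(v) for a, v in idx.items()}

    def date_span(self) -> tuple[dt.date, dt.date] | None:
        if not self.statements:
            return None
        dates = [s.date for s in self.statements]
        return min(dates), max(dates)


def _records_to_corpus(records: Iterable[Mapping[str, object]], origin: str) -> Corpus:
    records = list(records)
    if not records:
        raise EmptyCorpusError(f"{origin}: no statements found")
    keys = set(records[0].keys())
    missing = [c for c in REQUIRED_COLUMNS if c not in keys]
    if missing:
        raise SchemaError(f"{origin}: missing column(s): {', '.join(missing)}")
    statements = []
    for i, rec in enumerate(records, start=1):
        try:
            date = _parse_date(rec["date"])  # type: ignore[arg-type]
            stance = _parse_stance(rec["stance"])  # type: ignore[arg-type]
            sid = str(rec.get("statement_id") or "").strip() or f"s{i}"
            extra = {
                k: str(v) for k, v in rec.items() if k not in COLUMNS and v is not None
            }
            statements.append(
                Statement(
                    statement_id=sid,
                    article_id=str(rec["article_id"]),
                    source=str(rec["source"]),
                    date=date,
                    person=str(rec["person"]),
                    organization=str(rec["organization"]),
                    actor_type=str(rec["actor_type"]),
                    concept=str(rec["concept"]),
                    stance=stance,
                    extra=extra,
                )
            )
        except (ValueError, TypeError) as exc:
            raise RowError(i, str(exc)) from exc
    return Corpus(tuple(statements))


def read_statements(path: str | Path, format: str | None = None) -> Corpus:
    """Read a statement table from CSV or JSON.

    ``format`` is inferred from the file extension when not given.  Stance may
    be encoded as {1,0}, {true,false}, or {agree,disagree}; dates are
    ISO-8601.  Raises :class:`SchemaError` for missing columns,
    :class:`RowError` (with the row number) for unparseable values, and
    :class:`EmptyCorpusError` for a file with no statements.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise EmptyCorpusError(f"{path}: empty file")
            rows = list(reader)
        return _records_to_corpus(rows, str(path))
    if fmt == "json":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise SchemaError(f"{path}: JSON input must be an array of objects")
        return _records_to_corpus(data, str(path))
    raise ValueError(f"unknown format {fmt!r}")


def write_statements(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus back to the CSV or JSON dialect read by
    :func:`read_statements`; extra columns are appended after the canonical
    ones, in sorted order."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    records = [s.to_record() for s in corpus.statements]
    if fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(records, fh, indent=1)
            fh.write("\n")
        return
    extra_cols = sorted({k for r in records for k in r} - set(COLUMNS))
    fieldnames = list(COLUMNS) + extra_cols
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames, restval="")
        writer.writeheader()
        writer.writerows(records)


def slice_window(corpus: Corpus, start: dt.date, end: dt.date) -> Corpus:
    """Restrict a corpus to the half-open window [start, end).

    Half-open semantics make consecutive equal-length slices a partition of
    the corpus: no statement is lost or duplicated across adjacent windows.
    """
    if start >= end:
        raise IntervalError(f"window start {start} >= end {end}")
    kept = tuple(s for s in corpus.statements if start <= s.date < end)
    return Corpus(kept, window=(start, end))


def stratify_by_source(corpus: Corpus) -> dict[str, Corpus]:
    """Partition the corpus by publication source; parts are disjoint and
    their union is the input."""
    parts: dict[str, list[Statement]] = defaultdict(list)
    for s in corpus.statements:
        parts[s.source].append(s)
    return {src: Corpus(tuple(v), window=corpus.window) for src, v in sorted(parts.items())}


def actor_statement_counts(corpus: Corpus, level: ActorLevel = "organization") -> dict[str, int]:
    """Statement count per actor key at the chosen level (used for node
    sizing); counts sum to the corpus size."""
    counts: Counter[str] = Counter(s.actor(level) for s in corpus.statements)
    return dict(sorted(counts.items()))


def equal_windows(corpus: Corpus, n: int) -> list[tuple[dt.date, dt.date]]:
    """Split the corpus date span into ``n`` equal-length half-open windows
    covering every statement (the last window ends one day past the max
    date)."""
    span = corpus.date_span()
    if span is None:
        raise EmptyCorpusError("cannot window an empty corpus")
    if n < 1:
        raise IntervalError("need at least one window")
    start, last = span
    end = last + dt.timedelta(days=1)
    total = (end - start).days
    bounds = [start + dt.timedelta(days=round(i * total / n)) for i in range(n)] + [end]
    return [(bounds[i], bounds[i + 1]) for i in range(n)]
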