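"""Core domain types: time points, half-open intervals, tracks and features.

Time conventions used throughout the package:

* One study-wide, UTC-naive clock with **one second** as the finest
  resolution.  All duration arithmetic is integer seconds.
* Intervals are **half-open** ``[start, end)``: a point ``t`` belongs to the
  interval iff ``start <= t < end``.  Abutting intervals therefore partition
  time without double counting, and ``start == end`` denotes a zero-duration
  point event.
* Calendar dates (day-granular claims data) are promoted to midnight so that
  day-level and second-level data share one algebra.

A *track* is the time-dependent state of one statistical unit.  Two concrete
kinds exist: :class:`IntervalTrack` (a set of valued half-open intervals,
e.g. drug-exposure episodes or hypotension episodes) and
:class:`SignalTrack` (a piecewise-constant numeric function with possible
undefined gaps, e.g. a reconstructed arterial-pressure signal).  A
*feature* is the time-independent end product: one value per statistical
unit, ready for statistical analysis.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence, Union

from .errors import InputFormatError, MalformedTrackError

__all__ = [
    "TimePoint",
    "TrackValue",
    "promote_date",
    "as_timepoint",
    "seconds_between",
    "Interval",
    "IntervalRecord",
    "IntervalTrack",
    "coalesce",
    "total_duration",
    "SignalSegment",
    "SignalTrack",
    "StatisticalUnit",
    "Feature",
    "Exclusion",
    "UNIT_KINDS",
]

TimePoint = _dt.datetime
TrackValue = Union[int, float, str]

#: Statistical-unit kinds: the element of the population a study is conducted
#: on (a patient, a hospital stay, a surgical procedure, a single event such
#: as one drug administration).
UNIT_KINDS = frozenset(
    {"person", "visit", "visit_detail", "procedure_occurrence", "event_occurrence"}
)


def promote_date(d: Union[str, _dt.date, _dt.datetime]) -> TimePoint:
    """Return a calendar date as a TimePoint at midnight (00:00:00).

    Datetimes pass through (truncated to whole seconds); ISO-8601 strings are
    parsed as either a date or a datetime.  Invalid input raises
    :class:`~trackfeat.errors.InputFormatError`.
    """
    if isinstance(d, _dt.datetime):
        return d.replace(microsecond=0)
    if isinstance(d, _dt.date):
        return _dt.datetime(d.year, d.month, d.day)
    if isinstance(d, str):
        text = d.strip()
        for parser in (_dt.datetime.fromisoformat, _dt.date.fromisoformat):
            try:
                return promote_date(parser(text))
            except ValueError:
                continue
        raise InputFormatError(f"unparseable date/datetime: {d!r}")
    raise InputFormatError(f"unsupported date type: {type(d).__name__}")


#: Alias that reads better at call sites handling mixed date/datetime input.
as_timepoint = promote_date


def seconds_between(start: TimePoint, end: TimePoint) -> int:
    """Signed whole-second difference ``end - start``."""
    return round((end - start).total_seconds())


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open time interval ``[start, end)``; ``start == end`` is a point."""

    start: TimePoint
    end: TimePoint

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise MalformedTrackError(f"interval end before start: {self}")

    @property
    def duration_seconds(self) -> int:
        return seconds_between(self.start, self.end)

    @property
    def is_point(self) -> bool:
        return self.start == self.end

    def __contains__(self, t: TimePoint) -> bool:
        return self.start <= t < self.end

    def overlaps(self, other: "Interval") -> bool:
        """True when the two intervals share positive-duration time."""
        return self.start < other.end and other.start < self.end

    def intersection(self, other: "Interval") -> "Interval | None":
        """Set intersection, or None when empty.

        A point event at ``t`` intersects ``[a, b)`` iff ``a <= t < b``
        (half-open membership); two positive intervals intersect only on
        positive overlap.
        """
        lo = max(self.start, other.start)
        hi = min(self.end, other.end)
        if lo < hi:
            return Interval(lo, hi)
        if lo == hi:  # possible point intersection
            for p, w in ((self, other), (other, self)):
                if p.is_point and p.start in w:
                    return Interval(p.start, p.start)
        return None

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"[{self.start.isoformat()}, {self.end.isoformat()})"


@dataclass(frozen=True)
class IntervalRecord:
    """One valued interval of an :class:`IntervalTrack`.

    The value is the track state over the interval: ``1`` for a plain on/off
    state, a concept label for categorical tracks (e.g. the drug concept of an
    exposure episode), or a number.
    """

    interval: Interval
    value: TrackValue = 1

    @property
    def start(self) -> TimePoint:
        return self.interval.start

    @property
    def end(self) -> TimePoint:
        return self.interval.end


def _value_sort_key(v: TrackValue):
    # deterministic total order across mixed numeric/str values
    return (isinstance(v, str), str(v) if isinstance(v, str) else v)


@dataclass
class IntervalTrack:
    """Set of valued half-open intervals for one statistical unit."""

    unit_id: str
    track_concept: str
    records: list[IntervalRecord] = field(default_factory=list)
    source_value: str | None = None

    def __post_init__(self) -> None:
        self.records = [
            r if isinstance(r, IntervalRecord) else IntervalRecord(Interval(*r[0]), r[1])
            for r in self.records
        ]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[IntervalRecord]:
        return iter(self.records)

    @property
    def is_empty(self) -> bool:
        return not self.records

    def sorted_records(self) -> list[IntervalRecord]:
        return sorted(
            self.records, key=lambda r: (r.start, r.end, _value_sort_key(r.value))
        )

    def coalesce(self) -> "IntervalTrack":
        return coalesce(self)

    def covered(self) -> list[Interval]:
        """Union of covered time regardless of value, as disjoint intervals.

        Zero-duration point records are retained only where they fall outside
        every positive interval (they carry no duration but mark membership).
        """
        positive = sorted(
            (r.interval for r in self.records if not r.interval.is_point),
            key=lambda iv: (iv.start, iv.end),
        )
        merged: list[Interval] = []
        for iv in positive:
            if merged and iv.start <= merged[-1].end:
                if iv.end > merged[-1].end:
                    merged[-1] = Interval(merged[-1].start, iv.end)
            else:
                merged.append(iv)
        points = sorted(
            {
                r.start
                for r in self.records
                if r.interval.is_point and not any(r.start in m for m in merged)
            }
        )
        out = merged + [Interval(p, p) for p in points]
        out.sort(key=lambda iv: (iv.start, iv.end))
        return out

    def total_duration(self) -> int:
        return total_duration(self)

    def clip(self, window: Interval) -> "IntervalTrack":
        """Records clipped to ``window``; records with empty intersection drop."""
        kept = []
        for rec in self.sorted_records():
            inter = rec.interval.intersection(window)
            if inter is not None:
                kept.append(IntervalRecord(inter, rec.value))
        return replace(self, records=kept)

    def distinct_values(self) -> list[TrackValue]:
        return sorted({r.value for r in self.records}, key=_value_sort_key)


def coalesce(track: IntervalTrack) -> IntervalTrack:
    """Normal form of an interval track.

    Overlapping or abutting records **with equal value** merge into one
    (half-open semantics make ``[0,5)`` and ``[5,8)`` abut); records with
    distinct values never merge.  Point records subsumed by a same-valued
    interval are absorbed.  Output is sorted by (start, end, value); covered
    duration per distinct value is preserved.
    """
    by_value: dict = {}
    for rec in track.records:
        by_value.setdefault(rec.value, []).append(rec.interval)
    out: list[IntervalRecord] = []
    for value, intervals in by_value.items():
        intervals.sort(key=lambda iv: (iv.start, iv.end))
        merged: list[Interval] = []
        for iv in intervals:
            if merged and iv.is_point and merged[-1].is_point and iv == merged[-1]:
                continue  # duplicate point record
            if merged and iv.start <= merged[-1].end and not (
                iv.is_point and iv.start == merged[-1].end
            ):
                # abutting/overlapping; a point exactly at the open end does
                # not belong to [a, b) and stays separate
                if iv.end > merged[-1].end:
                    merged[-1] = Interval(merged[-1].start, iv.end)
            else:
                merged.append(iv)
        out.extend(IntervalRecord(iv, value) for iv in merged)
    out.sort(key=lambda r: (r.start, r.end, _value_sort_key(r.value)))
    return replace(track, records=out)


def total_duration(track: IntervalTrack) -> int:
    """Total covered time in seconds, counting each instant once
    regardless of how many values cover it."""
    return sum(iv.duration_seconds for iv in track.covered())


@dataclass(frozen=True)
class SignalSegment:
    """One constant piece of a signal: value ``value`` on ``[start, end)``."""

    interval: Interval
    value: float

    @property
    def start(self) -> TimePoint:
        return self.interval.start

    @property
    def end(self) -> TimePoint:
        return self.interval.end

    @property
    def duration_seconds(self) -> int:
        return self.interval.duration_seconds


@dataclass
class SignalTrack:
    """Piecewise-constant numeric signal for one statistical unit.

    Stored as an ordered list of disjoint constant segments inside ``domain``;
    time not covered by any segment is *undefined* (a gap, e.g. a monitor
    disconnection).  Between a segment's start and end the value is the
    segment value — last-observation-carried-forward semantics for
    reconstructed monitor data.
    """

    unit_id: str
    track_concept: str
    segments: list[SignalSegment]
    domain: Interval
    source_value: str | None = None

    def __post_init__(self) -> None:
        segs = sorted(
            (s for s in self.segments if not s.interval.is_point),
            key=lambda s: s.start,
        )
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise MalformedTrackError(
                    f"overlapping signal segments at {b.start.isoformat()}"
                )
        # canonical form: merge abutting equal-valued segments
        merged: list[SignalSegment] = []
        for s in segs:
            if merged and merged[-1].end == s.start and merged[-1].value == s.value:
                merged[-1] = SignalSegment(
                    Interval(merged[-1].start, s.end), s.value
                )
            else:
                merged.append(s)
        self.segments = merged

    @classmethod
    def from_breakpoints(
        cls,
        unit_id: str,
        track_concept: str,
        breakpoints: Sequence[tuple[TimePoint, float | None]],
        domain: Interval,
    ) -> "SignalTrack":
        """Build from (time, value) breakpoints; ``None`` opens an undefined gap.

        Each breakpoint's value holds until the next breakpoint (or the domain
        end for the last one).
        """
        pts = sorted(breakpoints, key=lambda p: p[0])
        segs: list[SignalSegment] = []
        for (t, v), nxt in zip(pts, list(pts[1:]) + [None]):
            if v is None:
                continue
            end = nxt[0] if nxt is not None else domain.end
            lo, hi = max(t, domain.start), min(end, domain.end)
            if lo < hi:
                segs.append(SignalSegment(Interval(lo, hi), float(v)))
        return cls(unit_id, track_concept, segs, domain)

    @property
    def is_defined_anywhere(self) -> bool:
        return bool(self.segments)

    def defined_duration(self) -> int:
        return sum(s.duration_seconds for s in self.segments)

    def value_at(self, t: TimePoint) -> float | None:
        """Signal value at instant ``t`` or None when undefined there."""
        if t not in self.domain and not (self.domain.is_point and t == self.domain.start):
            return None
        for s in self.segments:
            if t in s.interval:
                return s.value
        return None

    def clip(self, window: Interval) -> "SignalTrack":
        """Signal restricted to ``window`` (undefined outside it)."""
        segs = []
        for s in self.segments:
            inter = s.interval.intersection(window)
            if inter is not None and not inter.is_point:
                segs.append(SignalSegment(inter, s.value))
        dom = self.domain.intersection(window)
        if dom is None:
            dom = Interval(window.start, window.start)
        return SignalTrack(self.unit_id, self.track_concept, segs, dom, self.source_value)


@dataclass(frozen=True)
class StatisticalUnit:
    """The element of the study population one row of the final dataset
    describes: a patient, a hospital stay, a surgical procedure, or a single
    event occurrence.  Every unit resolves to exactly one person."""

    unit_id: str
    unit_kind: str
    person_id: str
    anchor_id: str | None = None
    visit_occurrence_id: str | None = None

    def __post_init__(self) -> None:
        if self.unit_kind not in UNIT_KINDS:
            raise ValueError(f"unknown unit kind: {self.unit_kind!r}")


@dataclass(frozen=True)
class Feature:
    """Time-independent (unit, label, value) triple — the analysis-ready
    variable.  Exactly one of ``value_number`` / ``value_concept`` is set;
    a feature carries no time field."""

    unit_id: str
    feature_concept: str
    value_number: float | None = None
    value_concept: str | None = None
    definition_id: str | None = None
    occurrence_id: str | None = None

    def __post_init__(self) -> None:
        if (self.value_number is None) == (self.value_concept is None):
            raise ValueError(
                "exactly one of value_number / value_concept must be present"
            )

    @property
    def value(self) -> TrackValue:
        return self.value_number if self.value_number is not None else self.value_concept


@dataclass(frozen=True)
class Exclusion:
    """Per-unit exclusion record: the unit could not yield a feature and why
    (missing milestone, signal undefined over the period, ...)."""

    unit_id: str
    reason: str
    detail: str | None = None
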