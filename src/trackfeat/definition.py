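"""Track definition: from raw event tables to per-unit, time-standardized tracks.

This module implements the first of the two transformations of the feature
extraction process: reducing the dimensions of raw clinical data to the
statistical unit of the study.  It covers

* selection of events through flat concept sets (with optional mapping of raw
  codes to wider categories, e.g. ATC codes to drug families),
* construction of interval tracks from paired date fields (hospital stays)
  and from exposure rows with a duration (drug dispensings),
* milestone selection by expert priority rule and period-of-interest
  construction with artificial offsets ("the 90 days before admission"),
* reconstruction of irregularly sampled physiological signals on a regular
  grid (last observation carried forward, with a validity horizon),
* detection of threshold-crossing episodes (hypotension, INR excursions),
* interval algebra between tracks (intersection, union, masking), and a few
  composite rules used by the reference study cases (drug–drug-interaction
  observation periods, minimum-event-count conditions).

All operations are deterministic.  Table-level operations take a pandas
DataFrame plus a :class:`UnitMap` and return a dict ``unit_id -> track``
together with a list of row-level rejects; track-level operations take and
return single-unit tracks.
"""

from __future__ import annotations

import datetime as _dt
import math
import operator
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    Interval,
    IntervalRecord,
    IntervalTrack,
    SignalSegment,
    SignalTrack,
    StatisticalUnit,
    TimePoint,
    coalesce,
    promote_date,
    seconds_between,
)
from .errors import (
    ConfigurationError,
    InputFormatError,
    MalformedTrackError,
    MissingMilestoneError,
)

__all__ = [
    "ConceptSetMember",
    "ConceptSet",
    "MilestoneRule",
    "WindowSpec",
    "UnitMap",
    "RowReject",
    "select_events",
    "interval_from_fields",
    "exposure_intervals",
    "shift_window",
    "select_milestone",
    "build_period",
    "resample",
    "reference_constant",
    "threshold_episodes",
    "filter_records",
    "intersect",
    "union",
    "restrict_signal",
    "transform_signal",
    "ddi_observation_period",
    "count_condition_track",
]

SECOND = _dt.timedelta(seconds=1)
DAY = _dt.timedelta(days=1)


def _as_seconds(x) -> int:
    if isinstance(x, _dt.timedelta):
        return round(x.total_seconds())
    return int(x)


def _as_timedelta(x) -> _dt.timedelta:
    return x if isinstance(x, _dt.timedelta) else _dt.timedelta(seconds=int(x))


# ---------------------------------------------------------------------------
# concept sets
# ---------------------------------------------------------------------------


def _normalize_code(vocabulary: str, code: str) -> str:
    code = str(code).strip()
    # ICD dialects write I95.1 or I951 interchangeably; compare dot-stripped
    if vocabulary.upper().startswith("ICD"):
        code = code.replace(".", "")
    return code


@dataclass(frozen=True)
class ConceptSetMember:
    vocabulary: str
    code: str
    is_prefix: bool = False
    target_concept: str | None = None


@dataclass
class ConceptSet:
    """Flat list of (vocabulary, code) pairs selecting clinical events.

    Matching is exact string comparison after ICD dot-stripping; a member
    flagged ``is_prefix`` matches any code it prefixes (e.g. ATC ``B01AA``
    matching ``B01AA03``).  A member with a ``target_concept`` maps the raw
    code to a wider category (active substance / administration-route family).
    """

    set_id: str
    members: list[ConceptSetMember] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for m in self.members:
            key = (m.vocabulary, m.code)
            if key in seen:
                raise ConfigurationError(
                    f"duplicate code {key} in concept set {self.set_id!r}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.members)

    def match(self, vocabulary: str, code: str) -> str | None:
        """Return the selected concept for a raw code, or None when outside
        the set.  The selected concept is the member's ``target_concept`` when
        defined, otherwise the raw code itself."""
        norm = _normalize_code(vocabulary, code)
        best: ConceptSetMember | None = None
        for m in self.members:
            if m.vocabulary != vocabulary:
                continue
            mcode = _normalize_code(vocabulary, m.code)
            if (m.is_prefix and norm.startswith(mcode)) or norm == mcode:
                # prefer the longest (most specific) matching member
                if best is None or len(mcode) > len(
                    _normalize_code(vocabulary, best.code)
                ):
                    best = m
        if best is None:
            return None
        return best.target_concept if best.target_concept else str(code)

    @classmethod
    def from_csv(cls, path) -> "dict[str, ConceptSet]":
        """Load concept sets from a delimited file with columns
        (set_id, vocabulary, code, is_prefix, target_concept)."""
        df = pd.read_csv(path, dtype=str).fillna("")
        required = {"set_id", "vocabulary", "code"}
        if not required.issubset(df.columns):
            raise InputFormatError(
                f"concept-set file {path} lacks columns {sorted(required - set(df.columns))}"
            )
        sets: dict[str, ConceptSet] = {}
        for set_id, grp in df.groupby("set_id", sort=True):
            members = [
                ConceptSetMember(
                    vocabulary=r["vocabulary"],
                    code=r["code"],
                    is_prefix=str(r.get("is_prefix", "")).strip().lower()
                    in {"1", "true", "yes"},
                    target_concept=(r.get("target_concept") or None),
                )
                for _, r in grp.iterrows()
            ]
            sets[str(set_id)] = cls(str(set_id), members)
        return sets


# ---------------------------------------------------------------------------
# unit resolution
# ---------------------------------------------------------------------------


@dataclass
class UnitMap:
    """Resolves raw table rows to statistical units.

    ``units`` registers every unit of the run; ``resolver`` maps one row
    (a pandas Series) to a unit_id or None when unresolvable.
    """

    units: dict[str, StatisticalUnit]
    resolver: Callable[[pd.Series], str | None]

    def resolve(self, row: pd.Series) -> str | None:
        uid = self.resolver(row)
        if uid is None or uid not in self.units:
            return None
        return uid

    @classmethod
    def by_column(cls, units: Mapping[str, StatisticalUnit], column: str) -> "UnitMap":
        """Rows carry the unit id directly (e.g. ``visit_occurrence_id``)."""

        def resolver(row: pd.Series):
            v = row.get(column)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else str(v)

        return cls(dict(units), resolver)

    @classmethod
    def by_person(cls, units: Mapping[str, StatisticalUnit]) -> "UnitMap":
        """Person-level studies: the person is the unit."""
        person_to_unit = {u.person_id: u.unit_id for u in units.values()}

        def resolver(row: pd.Series):
            return person_to_unit.get(str(row.get("person_id")))

        return cls(dict(units), resolver)

    @classmethod
    def by_mapping(
        cls,
        units: Mapping[str, StatisticalUnit],
        column: str,
        key_to_unit: Mapping[str, str],
    ) -> "UnitMap":
        """Rows carry a key (e.g. visit id) mapped to the unit it anchors
        (e.g. the surgical procedure performed during that visit)."""

        def resolver(row: pd.Series):
            v = row.get(column)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            return key_to_unit.get(str(v))

        return cls(dict(units), resolver)


@dataclass(frozen=True)
class RowReject:
    """A raw row that could not enter a track, with the reason."""

    row_index: int
    reason: str


# ---------------------------------------------------------------------------
# milestone / window specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MilestoneRule:
    """Priority rule selecting the main milestone event among candidates.

    ``candidate_concepts`` is ordered highest priority first (expert
    knowledge: e.g. induction event, then hypnotic administration, then
    intubation, then mechanical ventilation for the start of anesthesia).
    Among events of the selected concept, ``fallback`` "first"/"last" picks
    the earliest/latest; when no candidate concept is present at all,
    "error" excludes the unit.
    """

    candidate_concepts: tuple[str, ...]
    fallback: str = "first"

    def __post_init__(self) -> None:
        if not self.candidate_concepts:
            raise ConfigurationError("milestone rule needs at least one concept")
        if self.fallback not in {"first", "last", "error"}:
            raise ConfigurationError(f"unknown fallback {self.fallback!r}")


@dataclass(frozen=True)
class WindowSpec:
    """Artificial-period construction: anchor one endpoint of each record and
    apply signed offsets.  ``previous 90 days`` is
    ``WindowSpec("start", -90 days, 0)``."""

    anchor: str  # "start" | "end"
    offset_start: _dt.timedelta
    offset_end: _dt.timedelta

    def __post_init__(self) -> None:
        if self.anchor not in {"start", "end"}:
            raise ConfigurationError(f"window anchor must be start/end, got {self.anchor!r}")
        object.__setattr__(self, "offset_start", _as_timedelta(self.offset_start))
        object.__setattr__(self, "offset_end", _as_timedelta(self.offset_end))
        if self.offset_end < self.offset_start:
            raise ConfigurationError("window offsets invert the interval")


# ---------------------------------------------------------------------------
# raw table -> track operations
# ---------------------------------------------------------------------------


def _missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or (
        isinstance(v, str) and not v.strip()
    ) or v is pd.NaT


def _parse_point(raw) -> tuple[TimePoint, bool]:
    """Parse a raw cell into (TimePoint, day_granular?)."""
    if isinstance(raw, str):
        text = raw.strip()
        try:
            return promote_date(_dt.date.fromisoformat(text)), True
        except ValueError:
            return promote_date(text), False
    if isinstance(raw, _dt.datetime):
        p = promote_date(raw)
        return p, False
    if isinstance(raw, _dt.date):
        return promote_date(raw), True
    if isinstance(raw, pd.Timestamp):
        p = raw.to_pydatetime().replace(microsecond=0, tzinfo=None)
        return p, p.time() == _dt.time(0) and False
    raise InputFormatError(f"unparseable time cell: {raw!r}")


def _filter_and_map(
    df: pd.DataFrame,
    concept_set: ConceptSet | None,
    code_column: str | None,
    vocabulary: str | None,
) -> "list[tuple[int, pd.Series, object]]":
    """Yield (index, row, selected concept) for rows passing the concept set."""
    out = []
    for idx, row in df.iterrows():
        if concept_set is not None:
            if code_column is None or vocabulary is None:
                raise ConfigurationError(
                    "concept filtering needs code_column and vocabulary"
                )
            m = concept_set.match(vocabulary, row[code_column])
            if m is None:
                continue
            out.append((idx, row, m))
        else:
            out.append((idx, row, None))
    return out


def select_events(
    raw: pd.DataFrame,
    concepts: ConceptSet,
    unit_map: UnitMap,
    *,
    code_column: str,
    time_column: str,
    vocabulary: str,
    track_concept: str,
    value_column: str | None = None,
    on_unresolved: str = "drop",
) -> tuple[dict[str, IntervalTrack], list[RowReject]]:
    """Select timestamped point events through a concept set.

    One zero-length record per matching row; rows with codes outside the set
    are dropped; when the set defines a mapping target the record carries the
    mapped (wider) concept instead of the raw code.  With ``value_column``
    the record carries that column's numeric value instead (laboratory
    results such as INR, where the value — not the concept — feeds a later
    threshold rule).
    """
    if on_unresolved not in {"drop", "error"}:
        raise ConfigurationError(f"on_unresolved must be drop/error, got {on_unresolved!r}")
    tracks: dict[str, IntervalTrack] = {}
    rejects: list[RowReject] = []
    for idx, row, value in _filter_and_map(raw, concepts, code_column, vocabulary):
        uid = unit_map.resolve(row)
        if uid is None:
            if on_unresolved == "error":
                raise InputFormatError(f"row {idx}: unresolvable statistical unit")
            rejects.append(RowReject(idx, "unresolvable unit"))
            continue
        t, _ = _parse_point(row[time_column])
        if value_column is not None:
            value = float(row[value_column])
        track = tracks.setdefault(uid, IntervalTrack(uid, track_concept))
        track.records.append(IntervalRecord(Interval(t, t), value))
    return {u: coalesce(t) for u, t in tracks.items()}, rejects


def interval_from_fields(
    raw: pd.DataFrame,
    unit_map: UnitMap,
    *,
    start_field: str,
    end_field: str,
    track_concept: str,
    value=1,
    censor_end: TimePoint | None = None,
    on_unresolved: str = "drop",
) -> tuple[dict[str, IntervalTrack], list[RowReject]]:
    """Build one interval per row from paired start/end fields (e.g. a
    hospital stay from admission and discharge dates).

    Day-granular rows use the day-inclusive convention ``[admission,
    discharge + 1 day)`` so that a same-day stay occupies one full day.
    Rows with a missing end are censored at ``censor_end`` when given,
    rejected otherwise; rows with end before start are rejected.
    """
    tracks: dict[str, IntervalTrack] = {}
    rejects: list[RowReject] = []
    for idx, row in raw.iterrows():
        uid = unit_map.resolve(row)
        if uid is None:
            if on_unresolved == "error":
                raise InputFormatError(f"row {idx}: unresolvable statistical unit")
            rejects.append(RowReject(idx, "unresolvable unit"))
            continue
        try:
            start, start_day = _parse_point(row[start_field])
        except InputFormatError:
            rejects.append(RowReject(idx, f"unparseable {start_field}"))
            continue
        raw_end = row.get(end_field)
        if _missing(raw_end):
            if censor_end is None:
                rejects.append(RowReject(idx, f"missing {end_field}"))
                continue
            end = censor_end
        else:
            try:
                end, end_day = _parse_point(raw_end)
            except InputFormatError:
                rejects.append(RowReject(idx, f"unparseable {end_field}"))
                continue
            if end < start:
                rejects.append(RowReject(idx, "end before start"))
                continue
            if start_day and end_day:
                end = end + DAY  # discharge day is occupied
        if end < start:
            rejects.append(RowReject(idx, "end before start"))
            continue
        track = tracks.setdefault(uid, IntervalTrack(uid, track_concept))
        track.records.append(IntervalRecord(Interval(start, end), value))
    return {u: coalesce(t) for u, t in tracks.items()}, rejects


def exposure_intervals(
    raw: pd.DataFrame,
    unit_map: UnitMap,
    *,
    start_column: str = "drug_exposure_start_date",
    days_column: str = "days_supply",
    track_concept: str,
    value_column: str | None = None,
    concept_set: ConceptSet | None = None,
    code_column: str | None = None,
    vocabulary: str | None = None,
    on_unresolved: str = "drop",
) -> tuple[dict[str, IntervalTrack], list[RowReject]]:
    """Drug-exposure periods from administration date plus treatment duration.

    Each row becomes ``[start, start + days)``; a zero-day row still
    evidences exposure on the administration day and becomes a one-day
    period.  Negative durations are rejected.  When a concept set is given,
    rows are filtered through it and the record value is the selected
    (possibly mapped) concept; otherwise ``value_column`` (or constant 1)
    supplies the value.  Overlapping refills of the same value coalesce.
    """
    tracks: dict[str, IntervalTrack] = {}
    rejects: list[RowReject] = []
    for idx, row, mapped in _filter_and_map(raw, concept_set, code_column, vocabulary):
        uid = unit_map.resolve(row)
        if uid is None:
            if on_unresolved == "error":
                raise InputFormatError(f"row {idx}: unresolvable statistical unit")
            rejects.append(RowReject(idx, "unresolvable unit"))
            continue
        start, _ = _parse_point(row[start_column])
        d = row.get(days_column)
        days = 0 if _missing(d) else int(d)
        if days < 0:
            rejects.append(RowReject(idx, "negative duration"))
            continue
        end = start + _dt.timedelta(days=max(days, 1))
        if mapped is not None:
            value = mapped
        elif value_column is not None:
            value = row[value_column]
        else:
            value = 1
        track = tracks.setdefault(uid, IntervalTrack(uid, track_concept))
        track.records.append(IntervalRecord(Interval(start, end), value))
    return {u: coalesce(t) for u, t in tracks.items()}, rejects


# ---------------------------------------------------------------------------
# windows, milestones, periods
# ---------------------------------------------------------------------------


def shift_window(
    track: IntervalTrack, spec: WindowSpec, *, track_concept: str | None = None
) -> IntervalTrack:
    """Derive an artificial period from each record: pick the anchor endpoint
    and apply the offsets (e.g. previous-90-days, 10 minutes around an
    atropine administration)."""
    out = []
    for rec in track.sorted_records():
        anchor = rec.start if spec.anchor == "start" else rec.end
        s = anchor + spec.offset_start
        e = anchor + spec.offset_end
        if e < s:
            raise MalformedTrackError("window offsets invert the interval")
        out.append(IntervalRecord(Interval(s, e), rec.value))
    return IntervalTrack(
        track.unit_id, track_concept or track.track_concept, out, track.source_value
    )


def select_milestone(events: IntervalTrack, rule: MilestoneRule) -> TimePoint:
    """Select the main milestone among candidate events of one unit.

    The highest-priority concept present wins; among its events the rule's
    fallback picks first (earliest) or last.  With no candidate present,
    fallback "first"/"last" falls through to any event on the track, and
    "error" raises :class:`MissingMilestoneError` (the unit is excluded by
    the caller)."""
    by_concept: dict[str, list[TimePoint]] = {}
    for rec in events.records:
        by_concept.setdefault(str(rec.value), []).append(rec.start)
    for concept in rule.candidate_concepts:
        if concept == "*" and events.records:  # wildcard: any event qualifies
            times = [r.start for r in events.records]
            return min(times) if rule.fallback != "last" else max(times)
        if concept in by_concept:
            times = by_concept[concept]
            return min(times) if rule.fallback != "last" else max(times)
    if rule.fallback == "error" or not events.records:
        raise MissingMilestoneError(
            f"unit {events.unit_id}: no candidate milestone among "
            f"{list(rule.candidate_concepts)}"
        )
    times = [r.start for r in events.records]
    return min(times) if rule.fallback == "first" else max(times)


def build_period(
    start_milestone: TimePoint,
    end_milestone: TimePoint,
    *,
    offset_start: _dt.timedelta | int = 0,
    offset_end: _dt.timedelta | int = 0,
) -> Interval:
    """Period of interest from a start and an end milestone plus optional
    artificial offsets.  An inverted period raises
    :class:`~trackfeat.errors.MalformedTrackError`; a zero-length period is
    legal (aggregations over it return empty-period results)."""
    s = start_milestone + _as_timedelta(offset_start)
    e = end_milestone + _as_timedelta(offset_end)
    if e < s:
        raise MalformedTrackError(
            f"inverted period [{s.isoformat()}, {e.isoformat()})"
        )
    return Interval(s, e)


# ---------------------------------------------------------------------------
# signal reconstruction & transformation
# ---------------------------------------------------------------------------


def resample(
    samples: Sequence[tuple[TimePoint, float]] | pd.DataFrame,
    *,
    step: _dt.timedelta | int = SECOND,
    max_gap: _dt.timedelta | int = _dt.timedelta(seconds=600),
    domain: Interval,
    unit_id: str,
    track_concept: str,
    method: str = "locf",
    time_column: str = "measurement_datetime",
    value_column: str = "value_as_number",
) -> SignalTrack:
    """Reconstruct an irregularly sampled signal on a regular grid.

    The default reconstruction is last observation carried forward: each grid
    point takes the most recent sample value, but only while that sample is
    younger than ``max_gap`` (the validity horizon of monitor data — after a
    disconnection the signal is *undefined*, not stale).  Grid points before
    the first sample are undefined.  ``method="linear"`` interpolates between
    bracketing samples instead, leaving time outside the sampled range
    undefined.  No samples in the domain yields a fully undefined signal.
    """
    if isinstance(samples, pd.DataFrame):
        pairs = [
            (_parse_point(r[time_column])[0], float(r[value_column]))
            for _, r in samples.iterrows()
        ]
    else:
        pairs = [(promote_date(t), float(v)) for t, v in samples]
    pairs.sort(key=lambda p: p[0])
    step_s = _as_seconds(step)
    if step_s < 1:
        raise ConfigurationError("resampling step must be at least one second")
    gap_s = _as_seconds(max_gap)
    if method not in {"locf", "linear"}:
        raise ConfigurationError(f"unknown resampling method {method!r}")

    n = math.ceil(max(seconds_between(domain.start, domain.end), 0) / step_s)
    if n == 0 or not pairs:
        return SignalTrack(unit_id, track_concept, [], domain)

    t0 = domain.start
    times = np.array([seconds_between(t0, t) for t, _ in pairs], dtype=np.int64)
    vals = np.array([v for _, v in pairs], dtype=float)
    grid = np.arange(n, dtype=np.int64) * step_s

    if method == "locf":
        idx = np.searchsorted(times, grid, side="right") - 1
        defined = idx >= 0
        safe = np.clip(idx, 0, None)
        age = grid - times[safe]
        defined &= age <= gap_s
        values = vals[safe]
    else:  # linear interpolation between bracketing samples
        right = np.searchsorted(times, grid, side="right")
        defined = (right >= 1) & (right <= len(times) - 1)
        # also defined exactly at the last sample time
        defined |= (right == len(times)) & np.isin(grid, times)
        left = np.clip(right - 1, 0, len(times) - 1)
        rgt = np.clip(right, 0, len(times) - 1)
        span = times[rgt] - times[left]
        defined &= np.where(span > 0, span <= gap_s, True)
        values = np.interp(grid, times, vals)

    segments: list[SignalSegment] = []
    boundaries = np.flatnonzero(
        (defined[1:] != defined[:-1]) | (defined[1:] & (values[1:] != values[:-1]))
    )
    starts = np.concatenate(([0], boundaries + 1))
    ends = np.concatenate((boundaries + 1, [n]))
    for a, b in zip(starts, ends):
        if not defined[a]:
            continue
        seg_start = t0 + _dt.timedelta(seconds=int(grid[a]))
        seg_end = min(t0 + _dt.timedelta(seconds=int(grid[b - 1]) + step_s), domain.end)
        segments.append(SignalSegment(Interval(seg_start, seg_end), float(values[a])))
    return SignalTrack(unit_id, track_concept, segments, domain)


def reference_constant(
    signal: SignalTrack, reference_period: Interval, statistic: str = "mean"
) -> float | None:
    """Per-unit reference value: the time-weighted mean of the signal over a
    reference period (e.g. systolic pressure between arrival in the operating
    room and induction).  Returns None when the signal is undefined over the
    whole period — the caller excludes the unit with a logged reason."""
    if statistic != "mean":
        raise ConfigurationError(f"unsupported reference statistic {statistic!r}")
    clipped = signal.clip(reference_period)
    total = clipped.defined_duration()
    if total <= 0:
        return None
    weighted = sum(s.value * s.duration_seconds for s in clipped.segments)
    return weighted / total


_COMPARATORS: dict[str, Callable[[float, float], bool]] = {
    "<": operator.lt,
    "<=": operator.le,
    ">": operator.gt,
    ">=": operator.ge,
}


def threshold_episodes(
    signal: SignalTrack,
    comparator: str,
    threshold: float,
    *,
    reference: float | None = None,
    relative: bool = False,
    min_duration: _dt.timedelta | int = 0,
    merge_gap: _dt.timedelta | int = 0,
    track_concept: str = "episode",
) -> IntervalTrack:
    """Episodes where the signal satisfies a threshold condition.

    The threshold is either absolute or, with ``relative=True``, a fraction of
    a per-unit reference value (e.g. "below 90% of the baseline mean").
    Maximal defined stretches satisfying the comparator become candidate
    episodes; gaps no longer than ``merge_gap`` between consecutive episodes
    are bridged, then episodes shorter than ``min_duration`` are dropped
    (artifact rejection).  Both post-processing knobs default to off.
    """
    if comparator not in _COMPARATORS:
        raise ConfigurationError(f"unknown comparator {comparator!r}")
    if relative:
        if reference is None:
            raise ConfigurationError("fractional threshold requires a reference value")
        cut = threshold * reference
    else:
        cut = threshold
    cmp = _COMPARATORS[comparator]
    raw = IntervalTrack(
        signal.unit_id,
        track_concept,
        [
            IntervalRecord(s.interval, 1)
            for s in signal.segments
            if cmp(s.value, cut)
        ],
    )
    episodes = coalesce(raw).sorted_records()
    gap_s = _as_seconds(merge_gap)
    merged: list[Interval] = []
    for rec in episodes:
        if merged and seconds_between(merged[-1].end, rec.start) <= gap_s:
            if rec.end > merged[-1].end:
                merged[-1] = Interval(merged[-1].start, rec.end)
        else:
            merged.append(rec.interval)
    min_s = _as_seconds(min_duration)
    kept = [iv for iv in merged if iv.duration_seconds >= min_s]
    return IntervalTrack(
        signal.unit_id, track_concept, [IntervalRecord(iv, 1) for iv in kept]
    )


def filter_records(
    track: IntervalTrack,
    comparator: str,
    threshold: float,
    *,
    track_concept: str | None = None,
    keep_value: float | str | None = None,
) -> IntervalTrack:
    """Keep records whose numeric value satisfies a threshold condition
    (e.g. the laboratory-result points with INR >= 5).  ``keep_value``
    replaces the kept records' value (typically 1, turning the filtered
    result into an on/off episode track)."""
    if comparator not in _COMPARATORS:
        raise ConfigurationError(f"unknown comparator {comparator!r}")
    cmp = _COMPARATORS[comparator]
    kept = [
        IntervalRecord(r.interval, keep_value if keep_value is not None else r.value)
        for r in track.sorted_records()
        if not isinstance(r.value, str) and cmp(float(r.value), threshold)
    ]
    return IntervalTrack(
        track.unit_id, track_concept or track.track_concept, kept, track.source_value
    )


def restrict_signal(signal: SignalTrack, mask: IntervalTrack | Interval) -> SignalTrack:
    """Signal undefined outside the mask, unchanged inside (used to aggregate
    a signal "during the procedure")."""
    if isinstance(mask, Interval):
        windows = [mask]
    else:
        windows = [iv for iv in mask.covered() if not iv.is_point]
    segs: list[SignalSegment] = []
    for s in signal.segments:
        for w in windows:
            inter = s.interval.intersection(w)
            if inter is not None and not inter.is_point:
                segs.append(SignalSegment(inter, s.value))
    segs.sort(key=lambda s: s.start)
    return SignalTrack(
        signal.unit_id, signal.track_concept, segs, signal.domain, signal.source_value
    )


def transform_signal(
    signal: SignalTrack, per_unit_scalar: float, op: str
) -> SignalTrack:
    """Value-wise transformation by a per-unit scalar (e.g. tidal volume
    divided by ideal body weight).  Undefined segments stay undefined; a zero
    divisor raises :class:`ConfigurationError` and the caller excludes the
    unit."""
    ops = {
        "divide": lambda v: v / per_unit_scalar,
        "multiply": lambda v: v * per_unit_scalar,
        "subtract": lambda v: v - per_unit_scalar,
    }
    if op not in ops:
        raise ConfigurationError(f"unknown signal transform {op!r}")
    if op == "divide" and per_unit_scalar == 0:
        raise ConfigurationError("zero divisor for signal division")
    f = ops[op]
    return SignalTrack(
        signal.unit_id,
        signal.track_concept,
        [SignalSegment(s.interval, f(s.value)) for s in signal.segments],
        signal.domain,
        signal.source_value,
    )


# ---------------------------------------------------------------------------
# interval algebra between tracks
# ---------------------------------------------------------------------------


def _check_same_unit(a: IntervalTrack, b: IntervalTrack) -> None:
    if a.unit_id != b.unit_id:
        raise MalformedTrackError(
            f"track algebra across units: {a.unit_id!r} vs {b.unit_id!r}"
        )


def intersect(
    a: IntervalTrack, b: IntervalTrack, *, track_concept: str | None = None
) -> IntervalTrack:
    """Set intersection of covered time; the output carries ``a``'s values.

    ``a`` is the payload and ``b`` the mask: masking drug-exposure records by
    a 90-day window must keep the drug concepts for a later count-distinct.
    """
    _check_same_unit(a, b)
    mask = b.covered()
    out: list[IntervalRecord] = []
    for rec in a.sorted_records():
        for w in mask:
            inter = rec.interval.intersection(w)
            if inter is not None:
                out.append(IntervalRecord(inter, rec.value))
    return coalesce(
        IntervalTrack(
            a.unit_id,
            track_concept or f"{a.track_concept}/{b.track_concept}",
            out,
        )
    )


def union(
    a: IntervalTrack, b: IntervalTrack, *, track_concept: str | None = None
) -> IntervalTrack:
    """All records of both tracks, coalesced per distinct value; covered time
    is the set union.  Distinct values stay separate records so that a later
    count-distinct still sees every concept."""
    _check_same_unit(a, b)
    return coalesce(
        IntervalTrack(
            a.unit_id,
            track_concept or f"{a.track_concept}+{b.track_concept}",
            list(a.records) + list(b.records),
        )
    )


def ddi_observation_period(
    a: IntervalTrack,
    b: IntervalTrack,
    *,
    start_lag: _dt.timedelta = DAY,
    end_lag: _dt.timedelta = 4 * DAY,
    track_concept: str = "ddi_observation",
) -> IntervalTrack:
    """Drug–drug-interaction observation periods.

    For each maximal overlap episode ``[s, e)`` of the two exposure tracks the
    observation period starts the day after the two drugs were first
    administered together and ends four days after the first of the two drugs
    was discontinued: ``[s + 1 day, e + 4 days)``.  Re-exposure produces one
    period per overlap episode; degenerate periods are dropped.
    """
    _check_same_unit(a, b)
    overlap = intersect(
        IntervalTrack(a.unit_id, a.track_concept, [IntervalRecord(iv, 1) for iv in a.covered()]),
        b,
    )
    out = []
    for iv in overlap.covered():
        if iv.is_point:
            continue
        s = iv.start + start_lag
        e = iv.end + end_lag
        if s < e:
            out.append(IntervalRecord(Interval(s, e), 1))
    return IntervalTrack(a.unit_id, track_concept, out)


def count_condition_track(
    events: IntervalTrack,
    min_count: int,
    window: Interval | IntervalTrack,
    *,
    track_concept: str = "condition_met",
) -> IntervalTrack:
    """Unit-level boolean track: the window(s) where at least ``min_count``
    events fall (half-open membership; an event exactly at the window end is
    outside).  With an IntervalTrack of windows, each covered window is tested
    separately (e.g. "at least one INR >= 5 within each drug–drug-interaction
    observation period")."""
    if min_count < 1:
        raise ConfigurationError("min_count must be >= 1")
    windows = [window] if isinstance(window, Interval) else window.covered()
    out = []
    for w in windows:
        hits = len(events.clip(w).records)
        if hits >= min_count:
            out.append(IntervalRecord(w, 1))
    return IntervalTrack(events.unit_id, track_concept, out)
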