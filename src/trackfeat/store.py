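"""Persistence of tracks and features in OMOP-compatible TRACK / FEATURE tables.

The two tables extend the usual OMOP derived-element family (DRUG_ERA,
CONDITION_ERA, EPISODE, ...) with a generic store for intermediate tracks and
for the final analysis-ready features:

* ``TRACK`` keeps the time dimension (paired date/datetime start and end
  columns — claims data are day-granular, intraoperative signals are
  second-granular, and OMOP convention pairs the two precisions);
* ``FEATURE`` has no time columns at all; the time dimension is implicit in
  the value or the label.

Both carry the OMOP value split: continuous values in ``value_as_number``,
categorical values in ``value_as_concept_id``.  Signal tracks are stored as
one row per constant segment (abutting segment rows), not one row per raw
sample, to keep volume down.  Files are UTF-8 comma-delimited text with one
header row, ISO-8601 timestamps and empty string for absent values —
the common shape of OMOP CSV dumps.

Provenance conventions: ``track_source_value`` records the statistical unit
a row belongs to, and ``feature_source_value`` records the id of the
:class:`~trackfeat.aggregation.FeatureDefinition` that produced the feature;
a JSON sidecar manifest carries the full definitions and the unit registry,
so a run can be re-read losslessly.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .aggregation import FeatureDefinition
from .core import (
    Feature,
    Interval,
    IntervalRecord,
    IntervalTrack,
    SignalSegment,
    SignalTrack,
    StatisticalUnit,
    coalesce,
)
from .errors import InputFormatError, MalformedTrackError

__all__ = [
    "TRACK_COLUMNS",
    "FEATURE_COLUMNS",
    "DERIVED_TYPE_CONCEPT",
    "write_tracks",
    "read_tracks",
    "write_features",
    "read_features",
    "write_manifest",
    "read_manifest",
    "validate_tables",
    "Finding",
    "ValidationReport",
    "canonical",
]

Track = Union[IntervalTrack, SignalTrack]

TRACK_COLUMNS = [
    "track_id",
    "person_id",
    "track_concept_id",
    "track_type_concept_id",
    "track_start_date",
    "track_start_datetime",
    "track_end_date",
    "track_end_datetime",
    "value_as_number",
    "value_as_concept_id",
    "visit_occurrence_id",
    "visit_detail_id",
    "track_source_value",
]

FEATURE_COLUMNS = [
    "feature_id",
    "person_id",
    "feature_concept_id",
    "feature_type_concept_id",
    "value_as_number",
    "value_as_concept_id",
    "visit_occurrence_id",
    "visit_detail_id",
    "episode_id",
    "feature_source_value",
]

#: type-concept recorded for rows this package derives (provenance "type").
DERIVED_TYPE_CONCEPT = "derived_element"


def _fmt_dt(t: _dt.datetime) -> str:
    return t.replace(microsecond=0).isoformat(sep="T")


def _fmt_number(v) -> str:
    if isinstance(v, bool):
        return str(int(v))
    if isinstance(v, int):
        return str(v)
    return repr(float(v))


def _parse_number(s: str):
    try:
        return int(s)
    except ValueError:
        return float(s)


def canonical(track: Track) -> Track:
    """Canonical (storage) form of a track.

    Interval tracks coalesce and sort; signal tracks merge abutting
    equal-valued segments and shrink the domain to the defined span (the
    store keeps only defined segments, so undefined margins do not survive a
    round trip).  Free source text is dropped — ``track_source_value`` is the
    unit-provenance slot in storage.
    """
    if isinstance(track, SignalTrack):
        segs = list(track.segments)
        if segs:
            domain = Interval(segs[0].start, segs[-1].end)
        else:
            domain = Interval(track.domain.start, track.domain.start)
        return SignalTrack(track.unit_id, track.track_concept, segs, domain)
    out = coalesce(track)
    out.source_value = None
    return out


def _unit_fields(units: Mapping[str, StatisticalUnit] | None, unit_id: str):
    person_id, visit_id = unit_id, ""
    if units is not None and unit_id in units:
        u = units[unit_id]
        person_id = u.person_id
        if u.visit_occurrence_id:
            visit_id = u.visit_occurrence_id
        elif u.unit_kind == "visit":
            visit_id = u.unit_id
    return person_id, visit_id


def write_tracks(
    tracks: Iterable[Track],
    destination,
    *,
    units: Mapping[str, StatisticalUnit] | None = None,
    track_type_concept: str = DERIVED_TYPE_CONCEPT,
) -> int:
    """Write a collection of tracks as a TRACK table; returns the row count.

    One row per interval record / per constant signal segment; rows are
    sorted by (person_id, track_concept_id, start, end, value) and ids run
    sequentially from 1, so identical collections write byte-identical files.
    """
    rows = []
    for track in tracks:
        track = canonical(track)
        person_id, visit_id = _unit_fields(units, track.unit_id)
        if isinstance(track, SignalTrack):
            pieces: Sequence = track.segments
        else:
            pieces = track.records
        for piece in pieces:
            start, end = piece.start, piece.end
            if end < start:
                raise MalformedTrackError(
                    f"track {track.track_concept!r}/{track.unit_id!r}: end before start"
                )
            value = piece.value
            if isinstance(value, str):
                num, concept = "", value
            else:
                num, concept = _fmt_number(value), ""
            rows.append(
                {
                    "person_id": person_id,
                    "track_concept_id": track.track_concept,
                    "track_type_concept_id": track_type_concept,
                    "track_start_date": start.date().isoformat(),
                    "track_start_datetime": _fmt_dt(start),
                    "track_end_date": end.date().isoformat(),
                    "track_end_datetime": _fmt_dt(end),
                    "value_as_number": num,
                    "value_as_concept_id": concept,
                    "visit_occurrence_id": visit_id,
                    "visit_detail_id": "",
                    "track_source_value": track.unit_id,
                }
            )
    rows.sort(
        key=lambda r: (
            r["person_id"],
            r["track_concept_id"],
            r["track_source_value"],
            r["track_start_datetime"],
            r["track_end_datetime"],
            r["value_as_concept_id"],
            r["value_as_number"],
        )
    )
    for i, r in enumerate(rows, start=1):
        r["track_id"] = i
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS) if rows else pd.DataFrame(
        columns=TRACK_COLUMNS
    )
    df.to_csv(destination, index=False, lineterminator="\n")
    return len(rows)


@dataclass(frozen=True)
class _RowReject:
    line: int
    reason: str


def _require_columns(df: pd.DataFrame, required: Sequence[str], source) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputFormatError(f"{source}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{source}: ignoring extra columns {extra}", stacklevel=3)


def read_tracks(
    source,
    *,
    signal_concepts: Iterable[str] = (),
) -> tuple[list[Track], list[_RowReject]]:
    """Read a TRACK table back into track objects.

    Rows are grouped by (unit, concept) — the unit comes from
    ``track_source_value``, falling back to visit then person ids.  Concepts
    listed in ``signal_concepts`` reconstruct as signal tracks (their rows
    are constant segments with numeric values); everything else becomes an
    interval track.  Malformed rows are collected as rejects with their line
    number rather than aborting the read.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    _require_columns(df, TRACK_COLUMNS, source)
    signal_concepts = set(signal_concepts)
    rejects: list[_RowReject] = []
    grouped: dict[tuple[str, str], list[tuple]] = {}
    seen_ids: set[str] = set()
    for pos, row in df.iterrows():
        line = pos + 2  # header is line 1
        tid = row["track_id"]
        if tid in seen_ids:
            rejects.append(_RowReject(line, f"duplicate track_id {tid}"))
            continue
        seen_ids.add(tid)
        try:
            start = _dt.datetime.fromisoformat(row["track_start_datetime"])
            end = _dt.datetime.fromisoformat(row["track_end_datetime"])
        except ValueError:
            rejects.append(_RowReject(line, "unparseable datetime"))
            continue
        if end < start:
            rejects.append(_RowReject(line, "end before start"))
            continue
        num, concept = row["value_as_number"], row["value_as_concept_id"]
        if not num and not concept:
            rejects.append(_RowReject(line, "both value slots empty"))
            continue
        value = _parse_number(num) if num else concept
        unit_id = (
            row["track_source_value"]
            or row["visit_occurrence_id"]
            or row["person_id"]
        )
        grouped.setdefault((unit_id, row["track_concept_id"]), []).append(
            (start, end, value)
        )
    tracks: list[Track] = []
    for (unit_id, concept), pieces in grouped.items():
        pieces.sort(key=lambda p: (p[0], p[1]))
        if concept in signal_concepts:
            segs = [
                SignalSegment(Interval(s, e), float(v)) for s, e, v in pieces
            ]
            domain = Interval(pieces[0][0], max(p[1] for p in pieces))
            tracks.append(SignalTrack(unit_id, concept, segs, domain))
        else:
            recs = [IntervalRecord(Interval(s, e), v) for s, e, v in pieces]
            tracks.append(coalesce(IntervalTrack(unit_id, concept, recs)))
    tracks.sort(key=lambda t: (t.unit_id, t.track_concept))
    return tracks, rejects


def write_features(
    features: Iterable[Feature],
    destination,
    *,
    units: Mapping[str, StatisticalUnit] | None = None,
    feature_type_concept: str = DERIVED_TYPE_CONCEPT,
) -> int:
    """Write features as a FEATURE table; returns the row count.

    ``feature_source_value`` records the producing definition id (provenance
    is never dropped); ``episode_id`` discriminates several occurrences of a
    feature for one person — it holds the feature's ``occurrence_id`` when
    set, else the anchoring record id of sub-person statistical units.
    """
    rows = []
    for f in features:
        person_id, visit_id = _unit_fields(units, f.unit_id)
        episode = f.occurrence_id or ""
        if not episode and units is not None and f.unit_id in units:
            u = units[f.unit_id]
            if u.unit_kind in {"event_occurrence", "procedure_occurrence", "visit_detail"}:
                episode = u.anchor_id or u.unit_id
        rows.append(
            {
                "person_id": person_id,
                "feature_concept_id": f.feature_concept,
                "feature_type_concept_id": feature_type_concept,
                "value_as_number": "" if f.value_number is None else _fmt_number(f.value_number),
                "value_as_concept_id": f.value_concept or "",
                "visit_occurrence_id": visit_id,
                "visit_detail_id": "",
                "episode_id": episode,
                "feature_source_value": f.definition_id or "",
            }
        )
    rows.sort(
        key=lambda r: (
            r["person_id"],
            r["feature_concept_id"],
            r["visit_occurrence_id"],
            r["episode_id"],
            r["feature_source_value"],
            r["value_as_number"],
            r["value_as_concept_id"],
        )
    )
    for i, r in enumerate(rows, start=1):
        r["feature_id"] = i
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS) if rows else pd.DataFrame(
        columns=FEATURE_COLUMNS
    )
    df.to_csv(destination, index=False, lineterminator="\n")
    return len(rows)


def read_features(
    source,
    *,
    units: Mapping[str, StatisticalUnit] | None = None,
) -> list[Feature]:
    """Read a FEATURE table back into Feature objects.

    A duplicate ``feature_id`` or a row violating the one-value-slot
    invariant raises — the FEATURE table is the analysis product and must be
    internally consistent.  When a unit registry is given, each row is
    resolved back to its statistical unit (episode/anchor first, then visit,
    then person); otherwise the visit or person id stands in as the unit id.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    _require_columns(df, FEATURE_COLUMNS, source)
    by_anchor: dict[str, str] = {}
    by_visit: dict[str, str] = {}
    by_person: dict[str, str] = {}
    if units:
        for u in units.values():
            if u.unit_kind in {"event_occurrence", "procedure_occurrence", "visit_detail"}:
                by_anchor[u.anchor_id or u.unit_id] = u.unit_id
            elif u.unit_kind == "visit":
                by_visit[u.visit_occurrence_id or u.unit_id] = u.unit_id
            else:
                by_person[u.person_id] = u.unit_id
    seen: set[str] = set()
    out: list[Feature] = []
    for pos, row in df.iterrows():
        fid = row["feature_id"]
        if fid in seen:
            raise InputFormatError(f"{source}: duplicate feature_id {fid}")
        seen.add(fid)
        num, concept = row["value_as_number"], row["value_as_concept_id"]
        if bool(num) == bool(concept):
            raise InputFormatError(
                f"{source}: feature_id {fid}: exactly one value slot must be set"
            )
        unit_id = (
            by_anchor.get(row["episode_id"])
            or by_visit.get(row["visit_occurrence_id"])
            or by_person.get(row["person_id"])
            or row["visit_occurrence_id"]
            or row["person_id"]
        )
        out.append(
            Feature(
                unit_id=unit_id,
                feature_concept=row["feature_concept_id"],
                value_number=float(num) if num else None,
                value_concept=concept or None,
                definition_id=row["feature_source_value"] or None,
                occurrence_id=row["episode_id"] or None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------


def write_manifest(
    path,
    *,
    units: Mapping[str, StatisticalUnit] | None = None,
    definitions: Sequence[FeatureDefinition] = (),
    extra: Mapping | None = None,
) -> None:
    """JSON sidecar carrying the full feature definitions (the 7 items) and
    the statistical-unit registry of a run."""
    payload = {
        "units": {
            uid: {
                "unit_id": u.unit_id,
                "unit_kind": u.unit_kind,
                "person_id": u.person_id,
                "anchor_id": u.anchor_id,
                "visit_occurrence_id": u.visit_occurrence_id,
            }
            for uid, u in sorted((units or {}).items())
        },
        "definitions": [d.model_dump(mode="json") for d in definitions],
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> tuple[dict[str, StatisticalUnit], list[FeatureDefinition]]:
    payload = json.loads(Path(path).read_text())
    units = {
        uid: StatisticalUnit(
            unit_id=u["unit_id"],
            unit_kind=u["unit_kind"],
            person_id=u["person_id"],
            anchor_id=u.get("anchor_id"),
            visit_occurrence_id=u.get("visit_occurrence_id"),
        )
        for uid, u in payload.get("units", {}).items()
    }
    defs = [FeatureDefinition.model_validate(d) for d in payload.get("definitions", [])]
    return units, defs


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    table: str
    row_id: str
    rule: str
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(f.severity == "error" for f in self.findings)

    def add(self, severity, table, row_id, rule, message) -> None:
        self.findings.append(Finding(severity, table, str(row_id), rule, message))

    def to_text(self) -> str:
        if not self.findings:
            return "validation: no findings\n"
        lines = [
            f"{f.severity.upper()} {f.table}[{f.row_id}] {f.rule}: {f.message}"
            for f in self.findings
        ]
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "findings": [vars(f) for f in self.findings],
        }


def _read_id_set(path, column) -> set[str]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column not in df.columns:
        raise InputFormatError(f"{path}: missing column {column}")
    return set(df[column])


def validate_tables(
    track_file=None,
    feature_file=None,
    *,
    person_file=None,
    visit_file=None,
) -> ValidationReport:
    """Referential and structural validation of TRACK / FEATURE files.

    Findings cover orphan person/visit foreign keys (against the raw person
    and visit tables when supplied), inverted date order, rows with no value
    slot populated, duplicate primary keys, and date columns inconsistent
    with their datetime pair.  The report is machine-readable; an empty
    report means the files are internally and referentially consistent.
    """
    report = ValidationReport()
    persons = _read_id_set(person_file, "person_id") if person_file else None
    visits = _read_id_set(visit_file, "visit_occurrence_id") if visit_file else None

    def check_common(df, table, id_col, value_required=True):
        seen = set()
        for _, row in df.iterrows():
            rid = row[id_col]
            if rid in seen:
                report.add("error", table, rid, "duplicate_id", f"{id_col} repeated")
            seen.add(rid)
            if value_required and not row["value_as_number"] and not row["value_as_concept_id"]:
                report.add("error", table, rid, "empty_value", "both value slots empty")
            if persons is not None and row["person_id"] not in persons:
                report.add(
                    "error", table, rid, "orphan_person",
                    f"person_id {row['person_id']} not in person table",
                )
            if visits is not None and row["visit_occurrence_id"] and row[
                "visit_occurrence_id"
            ] not in visits:
                report.add(
                    "error", table, rid, "orphan_visit",
                    f"visit_occurrence_id {row['visit_occurrence_id']} not in visit table",
                )

    if track_file is not None:
        df = pd.read_csv(track_file, dtype=str, keep_default_na=False)
        _require_columns(df, TRACK_COLUMNS, track_file)
        check_common(df, "TRACK", "track_id")
        for _, row in df.iterrows():
            rid = row["track_id"]
            try:
                start = _dt.datetime.fromisoformat(row["track_start_datetime"])
                end = _dt.datetime.fromisoformat(row["track_end_datetime"])
            except ValueError:
                report.add("error", "TRACK", rid, "bad_datetime", "unparseable datetime")
                continue
            if end < start:
                report.add("error", "TRACK", rid, "date_order", "end before start")
            if row["track_start_date"] != start.date().isoformat() or row[
                "track_end_date"
            ] != end.date().isoformat():
                report.add(
                    "error", "TRACK", rid, "date_mismatch",
                    "date columns disagree with datetime columns",
                )
    if feature_file is not None:
        df = pd.read_csv(feature_file, dtype=str, keep_default_na=False)
        _require_columns(df, FEATURE_COLUMNS, feature_file)
        check_common(df, "FEATURE", "feature_id")
        for _, row in df.iterrows():
            if row["value_as_number"] and row["value_as_concept_id"]:
                report.add(
                    "error", "FEATURE", row["feature_id"], "double_value",
                    "both value slots populated",
                )
    return report
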