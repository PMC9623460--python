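"""Track aggregation: reducing a track over a period of interest to a feature.

The second transformation of the feature extraction process is deliberately
simple: a finite catalogue of extraction methods applied to one final track
over one period of interest per statistical unit.

Signal methods (``min``, ``max``, ``mean``/``weighted_average``, ``median``)
operate on the defined portion of a piecewise-constant signal restricted to
the period.  ``mean`` and ``weighted_average`` are the same operation — the
time-weighted mean — under the two names used in practice; on a signal
resampled to one measurement per second it coincides with the plain mean of
the per-second values.  ``median`` is defined as the median of the
one-second-grid values (grid anchored at the period start), which keeps it
deterministic and consistent with the resampling convention.

Interval methods (``sum_duration``, ``count``, ``count_distinct``,
``exists``, ``delay``, ``first``, ``last``) clip the track's records to the
period first.  Counting methods return the mathematically forced ``0`` on an
empty clip; value-like methods (``delay``, ``first``, ``last``) and all
signal methods over fully undefined periods yield *no* feature and an
exclusion record instead — silently imputing a value would corrupt the
downstream analysis.
"""

from __future__ import annotations

from typing import Any, Iterable, Mapping

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .core import (
    Exclusion,
    Feature,
    Interval,
    IntervalTrack,
    SignalTrack,
    seconds_between,
)
from .errors import ConfigurationError

__all__ = [
    "SIGNAL_METHODS",
    "INTERVAL_METHODS",
    "ExtractionMethod",
    "FeatureDefinition",
    "aggregate_signal",
    "aggregate_intervals",
    "run_definition",
    "threshold_feature",
]

SIGNAL_METHODS = frozenset({"min", "max", "mean", "median", "weighted_average"})
INTERVAL_METHODS = frozenset(
    {"sum_duration", "count", "count_distinct", "exists", "delay", "first", "last"}
)


class ExtractionMethod(BaseModel):
    """One method from the closed catalogue, with optional parameters
    (e.g. the grid step used by the median)."""

    name: str
    parameters: dict[str, Any] = Field(default_factory=dict)

    @field_validator("name")
    @classmethod
    def _known(cls, v: str) -> str:
        if v not in SIGNAL_METHODS | INTERVAL_METHODS:
            raise ValueError(f"unknown extraction method {v!r}")
        return v


class FeatureDefinition(BaseModel):
    """Declarative, re-loadable record of how a feature is computed.

    The seven documented items make the computation reproducible without
    reading the pipeline code: the raw ``source``, the ``statistical_unit``,
    the ``track_type`` concept, the ``value_rule`` (thresholds, mappings,
    windows — as text plus machine parameters), the ``final_track`` the
    aggregation reads, the ``period`` of interest, and the extraction
    ``method``.
    """

    definition_id: str
    feature_concept: str
    label: str
    # --- the 7 items ---
    source: str
    statistical_unit: str
    track_type: str
    value_rule: str
    final_track: str
    period: str
    method: ExtractionMethod

    value_rule_parameters: dict[str, Any] = Field(default_factory=dict)

    def items7(self) -> dict[str, str]:
        """The seven items as printable text (for ``describe``)."""
        return {
            "source": self.source,
            "statistical unit": self.statistical_unit,
            "type of track": self.track_type,
            "value rule": self.value_rule,
            "final track": self.final_track,
            "period of interest": self.period,
            "extraction method": self.method.name,
        }


def _grid_counts(track_like: SignalTrack) -> tuple[np.ndarray, np.ndarray]:
    """Per-second-grid (values, counts) of a clipped signal.  Segment
    boundaries share the whole-second resolution of the study clock, so each
    defined segment contributes exactly its duration in grid points."""
    vals, cnts = [], []
    for s in track_like.segments:
        n = s.duration_seconds
        if n > 0:
            vals.append(s.value)
            cnts.append(n)
    return np.asarray(vals, dtype=float), np.asarray(cnts, dtype=np.int64)


def _weighted_median(values: np.ndarray, counts: np.ndarray) -> float:
    """Median of the expanded per-second array, without expanding it."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    c = counts[order]
    cum = np.cumsum(c)
    n = int(cum[-1])
    lo_idx, hi_idx = (n - 1) // 2, n // 2
    lo = v[np.searchsorted(cum, lo_idx + 1)]
    hi = v[np.searchsorted(cum, hi_idx + 1)]
    return float((lo + hi) / 2.0)


def aggregate_signal(
    signal: SignalTrack, period: Interval, method: str
) -> float | None:
    """Aggregate a signal over a period; None when the signal is undefined
    throughout the period (the unit is excluded upstream)."""
    if method not in SIGNAL_METHODS:
        raise ConfigurationError(f"{method!r} is not a signal extraction method")
    clipped = signal.clip(period)
    values, counts = _grid_counts(clipped)
    if values.size == 0:
        return None
    if method == "min":
        return float(values.min())
    if method == "max":
        return float(values.max())
    if method in {"mean", "weighted_average"}:
        return float(np.dot(values, counts) / counts.sum())
    return _weighted_median(values, counts)


def aggregate_intervals(
    track: IntervalTrack, period: Interval, method: str
) -> float | int | str | None:
    """Aggregate an interval track over a period.

    Records are clipped to the period first (half-open semantics).  Counting
    methods return 0 on an empty clip; ``delay`` (seconds from the period
    start to the earliest clipped record), ``first`` and ``last`` (value of
    the earliest/latest clipped record, tie-broken by a stable sort on
    (start, value)) return None on an empty clip.
    """
    if method not in INTERVAL_METHODS:
        raise ConfigurationError(f"{method!r} is not an interval extraction method")
    clipped = track.clip(period)
    recs = clipped.sorted_records()
    if method == "sum_duration":
        return clipped.total_duration()
    if method == "count":
        return len(recs)
    if method == "count_distinct":
        return len(clipped.distinct_values())
    if method == "exists":
        return 1 if recs else 0
    if not recs:
        return None
    if method == "delay":
        return seconds_between(period.start, recs[0].start)
    if method == "first":
        return recs[0].value
    return recs[-1].value


_CMP = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
}


def threshold_feature(
    feature: Feature,
    comparator: str,
    threshold: float,
    *,
    feature_concept: str,
    definition_id: str | None = None,
) -> Feature:
    """Derive a 0/1 indicator feature from a numeric feature (e.g. guideline
    compliance: mean mL/kg below 8).  This is the only post-aggregation step
    in the catalogue: a comparison of a feature's value with a constant."""
    if comparator not in _CMP:
        raise ConfigurationError(f"unknown comparator {comparator!r}")
    if feature.value_number is None:
        raise ConfigurationError("threshold_feature needs a numeric feature")
    flag = 1.0 if _CMP[comparator](feature.value_number, threshold) else 0.0
    return Feature(
        feature.unit_id, feature_concept, value_number=flag,
        definition_id=definition_id or feature.definition_id,
        occurrence_id=feature.occurrence_id,
    )


_COUNTING = {"sum_duration", "count", "count_distinct", "exists"}


def run_definition(
    defn: FeatureDefinition,
    tracks: Mapping[str, Mapping[str, IntervalTrack | SignalTrack]],
    periods: Mapping[str, Mapping[str, Interval]],
) -> tuple[list[Feature], list[Exclusion]]:
    """Execute one feature definition over a collection of units.

    ``tracks`` maps track name -> (unit_id -> track); ``periods`` maps period
    name -> (unit_id -> period of interest).  The definition's ``final_track``
    and ``period`` must name entries of those collections (dangling references
    raise before any computation).  Exactly one feature per unit with a
    defined result is produced; every other unit appears in the exclusion
    report with a reason.  Deterministic: identical inputs give identical
    output order (sorted by unit_id).
    """
    if defn.final_track not in tracks:
        raise ConfigurationError(
            f"definition {defn.definition_id!r}: unknown final track {defn.final_track!r}"
        )
    if defn.period not in periods:
        raise ConfigurationError(
            f"definition {defn.definition_id!r}: unknown period {defn.period!r}"
        )
    track_map = tracks[defn.final_track]
    period_map = periods[defn.period]
    method = defn.method.name

    features: list[Feature] = []
    exclusions: list[Exclusion] = []
    for unit_id in sorted(period_map):
        period = period_map[unit_id]
        track = track_map.get(unit_id)
        if track is None:
            if method in _COUNTING:
                # an absent interval track is an empty one: zero is forced
                features.append(
                    Feature(unit_id, defn.feature_concept, value_number=0.0,
                            definition_id=defn.definition_id)
                )
            else:
                exclusions.append(Exclusion(unit_id, "no final track for unit"))
            continue
        if isinstance(track, SignalTrack):
            value = aggregate_signal(track, period, method)
            if value is None:
                exclusions.append(
                    Exclusion(unit_id, "signal undefined over the period")
                )
                continue
            features.append(
                Feature(unit_id, defn.feature_concept, value_number=float(value),
                        definition_id=defn.definition_id)
            )
        else:
            value = aggregate_intervals(track, period, method)
            if value is None:
                exclusions.append(
                    Exclusion(unit_id, f"no record in period for {method!r}")
                )
                continue
            if isinstance(value, str):
                features.append(
                    Feature(unit_id, defn.feature_concept, value_concept=value,
                            definition_id=defn.definition_id)
                )
            else:
                features.append(
                    Feature(unit_id, defn.feature_concept, value_number=float(value),
                            definition_id=defn.definition_id)
                )
    return features, exclusions
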