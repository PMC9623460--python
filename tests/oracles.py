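"""Independent brute-force oracles used by the tests.

Everything here works on an explicit per-second grid: intervals become
boolean membership arrays, signals become per-second value arrays, and the
statistics are computed with plain numpy on those arrays.  The oracles are
deliberately naive and share no code with the package's interval algebra or
aggregation, so agreement between the two is evidence, not tautology.
"""

from __future__ import annotations

import datetime as dt

import numpy as np

from trackfeat.core import Interval, IntervalRecord, IntervalTrack, SignalTrack

T0 = dt.datetime(2021, 1, 1)


def sec(t: int) -> dt.datetime:
    return T0 + dt.timedelta(seconds=int(t))


def iv(a: int, b: int) -> Interval:
    return Interval(sec(a), sec(b))


def rec(a: int, b: int, v=1) -> IntervalRecord:
    return IntervalRecord(iv(a, b), v)


def track(records, unit="u1", concept="t") -> IntervalTrack:
    return IntervalTrack(unit, concept, [rec(*r) for r in records])


def coverage(t: IntervalTrack, horizon: int) -> np.ndarray:
    """Boolean membership of each whole second in [0, horizon) under
    half-open semantics; zero-duration point records cover nothing."""
    out = np.zeros(horizon, dtype=bool)
    for r in t.records:
        a = int((r.start - T0).total_seconds())
        b = int((r.end - T0).total_seconds())
        out[max(a, 0): max(b, 0)] = True
    return out


def random_track(rng: np.random.Generator, horizon: int, max_records: int = 6,
                 values=(1,), unit="u1", concept="t") -> IntervalTrack:
    n = int(rng.integers(0, max_records + 1))
    records = []
    for _ in range(n):
        a = int(rng.integers(0, horizon))
        b = int(rng.integers(a, horizon + 1))
        v = values[int(rng.integers(0, len(values)))]
        records.append((a, b, v))
    return track(records, unit=unit, concept=concept)


def locf_per_second(samples, max_gap_s: int, horizon: int) -> list[float | None]:
    """Per-second LOCF reconstruction: value of the most recent sample at or
    before each second, None before the first sample or once the most recent
    sample is older than the validity horizon."""
    out: list[float | None] = []
    for g in range(horizon):
        prev = [(t, v) for t, v in samples if t <= g]
        if not prev:
            out.append(None)
            continue
        t, v = prev[-1]
        out.append(v if g - t <= max_gap_s else None)
    return out


def signal_per_second(signal: SignalTrack, lo: int, hi: int) -> list[float | None]:
    """The signal's value at each whole second of [lo, hi), None when
    undefined there."""
    return [signal.value_at(sec(g)) for g in range(lo, hi)]


def grid_stats(values: list[float | None]) -> dict[str, float] | None:
    defined = np.array([v for v in values if v is not None], dtype=float)
    if defined.size == 0:
        return None
    return {
        "min": float(defined.min()),
        "max": float(defined.max()),
        "mean": float(defined.mean()),
        "weighted_average": float(defined.mean()),
        "median": float(np.median(defined)),
    }


def random_signal(rng: np.random.Generator, horizon: int, unit="u1",
                  concept="s") -> SignalTrack:
    """Random piecewise-constant signal with undefined gaps on [0, horizon)."""
    from trackfeat.core import SignalSegment

    segs = []
    t = 0
    while t < horizon:
        dur = int(rng.integers(1, max(2, horizon // 4)))
        end = min(t + dur, horizon)
        if rng.random() < 0.75:  # else leave an undefined gap
            segs.append(SignalSegment(iv(t, end), float(rng.integers(50, 150))))
        t = end
    return SignalTrack(unit, concept, segs, iv(0, horizon))
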