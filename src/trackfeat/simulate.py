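"""Deterministic generator of OMOP-style raw tables with planted ground truth.

Each scenario emulates the raw data one of the eight reference study cases
needs — irregular intraoperative vital signs, anesthesia milestone events,
drug exposures with a duration, daily INR results, day-granular hospital
stays — together with an *answer key* holding the true value of every target
feature, so the whole pipeline can be tested end to end without any external
data.

Exactness by construction: physiological signals are generated as
ground-truth **step functions first** and then sampled at irregular
intervals whose sample set always contains every change point of the truth.
Last-observation-carried-forward reconstruction of such samples reproduces
the truth exactly, so planted durations and means are sharp, not
approximate.  Additive noise is off by default; when enabled, the truth is
defined on the noisy step function (the sampled values), keeping the answer
key exact.  Sampling irregularity therefore never changes the planted
truths.

One seeded pseudo-random stream (`numpy.random.default_rng`) drives a run;
the same seed yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import vocab
from .core import Interval, IntervalRecord, IntervalTrack, StatisticalUnit
from .errors import ConfigurationError

__all__ = ["SCENARIOS", "ScenarioSpec", "Bundle", "generate", "generate_worked_sc6_fixture"]

SCENARIOS = ("sc1", "sc2", "sc3", "sc4", "sc5", "sc6", "sc7", "sc8")

EPOCH = _dt.datetime(2021, 1, 1)
DAY = _dt.timedelta(days=1)

TABLE_COLUMNS = {
    "person": ["person_id", "year_of_birth", "gender_concept_id", "ideal_body_weight"],
    "visit_occurrence": [
        "visit_occurrence_id", "person_id", "visit_concept_id",
        "visit_start_date", "visit_end_date", "eligible",
    ],
    "drug_exposure": [
        "drug_exposure_id", "person_id", "visit_occurrence_id", "drug_concept_id",
        "drug_exposure_start_date", "drug_exposure_start_datetime", "days_supply",
    ],
    "measurement": [
        "measurement_id", "person_id", "visit_occurrence_id",
        "measurement_concept_id", "measurement_datetime", "value_as_number",
    ],
    "procedure_occurrence": [
        "procedure_occurrence_id", "person_id", "visit_occurrence_id",
        "procedure_concept_id", "procedure_datetime",
    ],
}

#: visit_concept_id per scenario — lets case pipelines select their own care
#: setting even inside a mixed bundle.
VISIT_CONCEPTS = {
    "sc1": "icu_stay",
    "sc2": "heavy_surgery",
    "sc3": "cesarean_section",
    "sc4": "bradycardia_surgery",
    "sc5": "ventilated_surgery",
    "sc6": "hospital_stay",
    "sc7": "ambulatory_care",
    "sc8": "ambulatory_care",
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Study conditions of one simulated scenario.

    Signal parameters: ``baseline`` (scenario-typical level when None),
    additive per-sample ``noise_sd`` (off by default), and the
    inter-sample-gap bounds in seconds (uniform 15–120 s, typical monitor
    archiving).  Planted-event parameters: how many below/above-threshold
    episodes to plant and their duration/depth, how many flagged drugs fall
    inside/outside an aggregation window, how many drug–drug-interaction
    overlap episodes a patient has.  All distributions are parameterized
    here; nothing else is random.
    """

    scenario: str
    n_units: int = 50
    seed: int = 42
    # signal generation
    baseline: float | None = None
    noise_sd: float = 0.0
    gap_min_s: int = 15
    gap_max_s: int = 120
    # planted threshold episodes
    max_episodes: int = 3
    episode_min_s: int = 60
    episode_max_s: int = 600
    episode_depth: float = 0.82  # episode level as a fraction of the reference
    # drug-window scenarios
    max_in_window: int = 4
    max_out_window: int = 2
    max_overlaps: int = 2

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS + ("mixed",):
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        if self.n_units < 1:
            raise ConfigurationError("n_units must be >= 1")
        if self.gap_min_s < 1 or self.gap_max_s < self.gap_min_s:
            raise ConfigurationError("invalid sampling-gap bounds")
        if self.episode_min_s < 1 or self.episode_max_s < self.episode_min_s:
            raise ConfigurationError("invalid episode-duration bounds")


@dataclass
class Bundle:
    """Raw table bundle plus answer key and the statistical-unit registry."""

    scenario: str
    tables: dict[str, pd.DataFrame]
    units: dict[str, StatisticalUnit]
    answer_key: pd.DataFrame  # columns: unit_id, feature_concept, true_value

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, columns in TABLE_COLUMNS.items():
            df = self.tables.get(name, pd.DataFrame(columns=columns))
            df.to_csv(out / f"{name}.csv", index=False, lineterminator="\n")
        self.answer_key.to_csv(out / "answer_key.csv", index=False, lineterminator="\n")

    @classmethod
    def read(cls, in_dir, scenario: str = "unknown") -> "Bundle":
        """Load a written bundle (units are rebuilt by the case pipelines)."""
        inp = Path(in_dir)
        tables = {
            name: pd.read_csv(inp / f"{name}.csv", dtype=str, keep_default_na=False)
            for name in TABLE_COLUMNS
            if (inp / f"{name}.csv").exists()
        }
        key_path = inp / "answer_key.csv"
        key = (
            pd.read_csv(key_path, dtype=str, keep_default_na=False)
            if key_path.exists()
            else pd.DataFrame(columns=["unit_id", "feature_concept", "true_value"])
        )
        return cls(scenario, tables, {}, key)


class _Builder:
    """Accumulates rows with sequential ids and an answer key."""

    def __init__(self, prefix: str = "") -> None:
        self.prefix = prefix
        self.rows: dict[str, list[dict]] = {name: [] for name in TABLE_COLUMNS}
        self.units: dict[str, StatisticalUnit] = {}
        self.answers: list[dict] = []
        self._counters: dict[str, int] = {}

    def next_id(self, kind: str) -> str:
        n = self._counters.get(kind, 0) + 1
        self._counters[kind] = n
        return f"{self.prefix}{kind}{n:04d}"

    def person(self, *, year_of_birth: int = 1960, ibw: float | None = None) -> str:
        pid = self.next_id("p")
        self.rows["person"].append(
            {
                "person_id": pid,
                "year_of_birth": year_of_birth,
                "gender_concept_id": "unknown",
                "ideal_body_weight": "" if ibw is None else repr(float(ibw)),
            }
        )
        return pid

    def visit(self, pid: str, concept: str, start, end, *, eligible: str = "") -> str:
        vid = self.next_id("v")
        self.rows["visit_occurrence"].append(
            {
                "visit_occurrence_id": vid,
                "person_id": pid,
                "visit_concept_id": concept,
                "visit_start_date": start,
                "visit_end_date": end,
                "eligible": eligible,
            }
        )
        return vid

    def drug(self, pid, vid, code, start_date, days, *, start_datetime="") -> str:
        did = self.next_id("d")
        self.rows["drug_exposure"].append(
            {
                "drug_exposure_id": did,
                "person_id": pid,
                "visit_occurrence_id": vid,
                "drug_concept_id": code,
                "drug_exposure_start_date": start_date,
                "drug_exposure_start_datetime": start_datetime,
                "days_supply": days,
            }
        )
        return did

    def measurement(self, pid, vid, concept, when: _dt.datetime, value: float) -> None:
        self.rows["measurement"].append(
            {
                "measurement_id": self.next_id("m"),
                "person_id": pid,
                "visit_occurrence_id": vid,
                "measurement_concept_id": concept,
                "measurement_datetime": when.isoformat(),
                "value_as_number": repr(float(value)),
            }
        )

    def procedure(self, pid, vid, concept, when: _dt.datetime) -> str:
        prid = self.next_id("proc")
        self.rows["procedure_occurrence"].append(
            {
                "procedure_occurrence_id": prid,
                "person_id": pid,
                "visit_occurrence_id": vid,
                "procedure_concept_id": concept,
                "procedure_datetime": when.isoformat(),
            }
        )
        return prid

    def unit(self, unit_id: str, kind: str, pid: str, *, anchor=None, visit=None) -> None:
        self.units[unit_id] = StatisticalUnit(unit_id, kind, pid, anchor, visit)

    def answer(self, unit_id: str, concept: str, value) -> None:
        self.answers.append(
            {"unit_id": unit_id, "feature_concept": concept, "true_value": value}
        )

    def bundle(self, scenario: str) -> Bundle:
        tables = {
            name: pd.DataFrame(rows, columns=TABLE_COLUMNS[name])
            for name, rows in self.rows.items()
        }
        key = pd.DataFrame(
            self.answers, columns=["unit_id", "feature_concept", "true_value"]
        )
        return Bundle(scenario, tables, dict(self.units), key)


# ---------------------------------------------------------------------------
# step-function machinery (ground truth first, samples second)
# ---------------------------------------------------------------------------


def _plant_episodes(
    rng: np.random.Generator,
    spec: ScenarioSpec,
    lo_s: int,
    hi_s: int,
) -> list[tuple[int, int]]:
    """Non-overlapping planted episodes (offsets in seconds) inside [lo, hi)."""
    k = int(rng.integers(0, spec.max_episodes + 1))
    episodes: list[tuple[int, int]] = []
    cursor = lo_s
    for _ in range(k):
        dur = int(rng.integers(spec.episode_min_s, spec.episode_max_s + 1))
        latest = hi_s - dur
        if cursor > latest:
            break
        start = int(rng.integers(cursor, latest + 1))
        episodes.append((start, start + dur))
        cursor = start + dur + 30  # keep episodes separated
    return episodes


def _truth_segments(
    total_s: int, baseline: float, episodes: list[tuple[int, int]], level: float
) -> list[tuple[int, int, float]]:
    """Piecewise-constant truth: baseline everywhere, ``level`` on episodes."""
    segs: list[tuple[int, int, float]] = []
    cursor = 0
    for s, e in sorted(episodes):
        if cursor < s:
            segs.append((cursor, s, baseline))
        segs.append((s, e, level))
        cursor = e
    if cursor < total_s:
        segs.append((cursor, total_s, baseline))
    return segs


def _truth_value(segs: list[tuple[int, int, float]], t: int) -> float:
    for s, e, v in segs:
        if s <= t < e:
            return v
    return segs[-1][2]


def _sample_offsets(
    rng: np.random.Generator, total_s: int, gap_min: int, gap_max: int,
    change_points: list[int],
) -> list[int]:
    """Irregular sample times (seconds) covering [0, total); always includes
    0 and every truth change point, so LOCF reconstruction is exact."""
    times = {0}
    t = 0
    while True:
        t += int(rng.integers(gap_min, gap_max + 1))
        if t >= total_s:
            break
        times.add(t)
    times.update(cp for cp in change_points if 0 <= cp < total_s)
    return sorted(times)


def _emit_signal(
    b: _Builder,
    rng: np.random.Generator,
    spec: ScenarioSpec,
    *,
    pid: str,
    vid: str,
    concept: str,
    t0: _dt.datetime,
    segs: list[tuple[int, int, float]],
) -> list[tuple[int, int, float]]:
    """Write measurement rows sampling a truth step function; returns the
    effective truth (identical to ``segs`` unless noise is on, in which case
    the truth is the sampled noisy step function)."""
    total_s = segs[-1][1]
    change_points = [s for s, _, _ in segs]
    offsets = _sample_offsets(rng, total_s, spec.gap_min_s, spec.gap_max_s, change_points)
    values = [_truth_value(segs, t) for t in offsets]
    if spec.noise_sd > 0:
        values = [v + float(rng.normal(0.0, spec.noise_sd)) for v in values]
        effective = [
            (t, nxt if i + 1 < len(offsets) else total_s, values[i])
            for i, (t, nxt) in enumerate(
                zip(offsets, offsets[1:] + [total_s])
            )
        ]
        effective = [(s, e, v) for s, e, v in effective if e > s]
    else:
        effective = segs
    for t, v in zip(offsets, values):
        b.measurement(pid, vid, concept, t0 + _dt.timedelta(seconds=t), v)
    return effective


def _weighted_mean(segs: list[tuple[int, int, float]], lo: int, hi: int) -> float | None:
    num = den = 0.0
    for s, e, v in segs:
        a, z = max(s, lo), min(e, hi)
        if z > a:
            num += v * (z - a)
            den += z - a
    return num / den if den else None


def _per_second_stats(
    segs: list[tuple[int, int, float]], lo: int, hi: int
) -> dict[str, float] | None:
    """Brute-force per-second min/max/median within [lo, hi) — used for
    planted answer keys on short windows."""
    expanded: list[float] = []
    for s, e, v in segs:
        expanded.extend([v] * (min(e, hi) - max(s, lo)) if min(e, hi) > max(s, lo) else [])
    if not expanded:
        return None
    arr = np.asarray(expanded, dtype=float)
    return {
        "min": float(arr.min()),
        "max": float(arr.max()),
        "median": float(np.median(arr)),
    }


def _iso_day(d: _dt.date | _dt.datetime) -> str:
    return (d.date() if isinstance(d, _dt.datetime) else d).isoformat()


# ---------------------------------------------------------------------------
# scenario generators
# ---------------------------------------------------------------------------


def _gen_sc1(b: _Builder, rng: np.random.Generator, spec: ScenarioSpec) -> None:
    """ICU stays with irregular PaO2 sampling; feature: time-weighted mean of
    the reconstructed signal over the first 24 h of the stay, for eligible
    (mechanically ventilated, septic-shock) stays."""
    for i in range(spec.n_units):
        pid = b.person(year_of_birth=int(rng.integers(1940, 1990)))
        t0 = EPOCH + _dt.timedelta(days=i, hours=int(rng.integers(0, 24)))
        stay_h = int(rng.integers(30, 96))
        vid = b.visit(
            pid, VISIT_CONCEPTS["sc1"], t0.isoformat(),
            (t0 + _dt.timedelta(hours=stay_h)).isoformat(),
            eligible="1" if rng.random() < 0.8 else "0",
        )
        b.unit(vid, "visit", pid, visit=vid)
        baseline = spec.baseline if spec.baseline is not None else float(
            np.round(rng.uniform(80.0, 120.0), 1)
        )
        total_s = 24 * 3600
        episodes = _plant_episodes(rng, spec, 600, total_s - 600)
        level = float(np.round(baseline * rng.uniform(1.3, 1.8), 1))  # hyperoxemic
        segs = _truth_segments(total_s, baseline, episodes, level)
        segs = _emit_signal(b, rng, spec, pid=pid, vid=vid, concept=vocab.PAO2,
                            t0=t0, segs=segs)
        eligible = b.rows["visit_occurrence"][-1]["eligible"] == "1"
        if eligible:
            b.answer(vid, "pao2_weighted_mean", _weighted_mean(segs, 0, total_s))


def _gen_anesthesia_case(
    b: _Builder, rng: np.random.Generator, spec: ScenarioSpec, case: str
) -> None:
    """Shared generator for the two hypotension cases.

    sc2: mean arterial pressure during heavy surgery; reference = mean over
    the pre-incision baseline window; truth = seconds below 90 % of it.
    sc3: systolic pressure during cesarean section; the anesthesia start may
    be documented by up to four concepts (expert priority rule) and the
    reference window runs from arrival in the operating room to the selected
    induction; truth = seconds below 80 % of the reference between induction
    and birth.
    """
    depth = spec.episode_depth if case == "sc2" else min(spec.episode_depth, 0.75)
    concept = vocab.MAP if case == "sc2" else vocab.SAP
    for i in range(spec.n_units):
        pid = b.person(year_of_birth=int(rng.integers(1950, 2000)))
        t0 = EPOCH + _dt.timedelta(days=i, hours=8)
        baseline = spec.baseline if spec.baseline is not None else float(
            np.round(rng.uniform(80.0, 95.0) if case == "sc2" else rng.uniform(105.0, 140.0), 1)
        )
        if case == "sc2":
            proc_s = int(rng.integers(5400, 3600 * 4))
            t_end = t0 + _dt.timedelta(seconds=proc_s)
            vid = b.visit(pid, VISIT_CONCEPTS[case], t0.isoformat(), t_end.isoformat())
            anchor = b.procedure(pid, vid, vocab.ANESTHESIA_START, t0)
            t_ref_end = t0 + _dt.timedelta(seconds=int(rng.integers(300, 900)))
            b.procedure(pid, vid, vocab.INCISION, t_ref_end)
            b.procedure(pid, vid, vocab.ANESTHESIA_END, t_end)
            dip_lo = int((t_ref_end - t0).total_seconds()) + 60
            period_lo, period_hi = 0, proc_s
            threshold = 0.9
        else:
            t_ind = t0 + _dt.timedelta(seconds=int(rng.integers(300, 900)))
            present = [vocab.ANESTHESIA_START_PRIORITY[0]] if rng.random() < 0.6 else []
            # lower-priority documentation of the same start event
            offsets = {vocab.INDUCTION: 0, vocab.HYPNOTIC: -60,
                       vocab.INTUBATION: 120, vocab.VENTILATION: 180}
            for c in vocab.ANESTHESIA_START_PRIORITY[1:]:
                if rng.random() < 0.5:
                    present.append(c)
            if not present:
                present = [vocab.VENTILATION]
            selected = next(
                c for c in vocab.ANESTHESIA_START_PRIORITY if c in present
            )
            t_sel = t_ind + _dt.timedelta(seconds=offsets[selected])
            t_birth = t_sel + _dt.timedelta(seconds=int(rng.integers(1200, 2400)))
            t_end = t_birth + _dt.timedelta(seconds=int(rng.integers(120, 600)))
            proc_s = int((t_end - t0).total_seconds())
            vid = b.visit(pid, VISIT_CONCEPTS[case], t0.isoformat(), t_end.isoformat())
            anchor = b.procedure(pid, vid, vocab.OR_ARRIVAL, t0)
            for c in present:
                b.procedure(pid, vid, c, t_ind + _dt.timedelta(seconds=offsets[c]))
            b.procedure(pid, vid, vocab.BIRTH, t_birth)
            dip_lo = int((t_ind - t0).total_seconds()) + 300
            period_lo = int((t_sel - t0).total_seconds())
            period_hi = int((t_birth - t0).total_seconds())
            threshold = 0.8
        # the statistical unit is the procedure, anchored (and identified) by
        # the procedure row documenting its start
        uid = anchor
        b.unit(uid, "procedure_occurrence", pid, anchor=anchor, visit=vid)
        level = float(np.round(baseline * depth, 1))
        episodes = _plant_episodes(rng, spec, dip_lo, period_hi - 60)
        segs = _truth_segments(proc_s, baseline, episodes, level)
        segs = _emit_signal(b, rng, spec, pid=pid, vid=vid, concept=concept,
                            t0=t0, segs=segs)
        # truth: seconds strictly below threshold*reference inside the period
        ref = _weighted_mean(segs, 0, dip_lo - 60 if case == "sc2" else period_lo)
        cut = threshold * (ref if ref is not None else baseline)
        below = sum(
            min(e, period_hi) - max(s, period_lo)
            for s, e, v in segs
            if v < cut and min(e, period_hi) > max(s, period_lo)
        )
        target = "map_hypotension_duration_s" if case == "sc2" else "sap_hypotension_duration_s"
        b.answer(uid, target, below)


def _gen_sc4(b: _Builder, rng: np.random.Generator, spec: ScenarioSpec) -> None:
    """Atropine administrations during surgery with a heart-rate signal; the
    statistical unit is the administration event.  Features: median/min/max
    heart rate in the 10 minutes before and after each administration,
    clipped to the procedure."""
    made = 0
    i = 0
    while made < spec.n_units:
        pid = b.person()
        t0 = EPOCH + _dt.timedelta(days=i, hours=9)
        i += 1
        proc_s = 2 * 3600
        vid = b.visit(pid, VISIT_CONCEPTS["sc4"],
                      t0.isoformat(), (t0 + _dt.timedelta(seconds=proc_s)).isoformat())
        # heart-rate step function: a new level at every sample
        offsets = _sample_offsets(rng, proc_s, 30, 90, [])
        values = np.clip(
            70 + np.cumsum(rng.integers(-6, 7, size=len(offsets))), 40, 130
        ).astype(float)
        for t, v in zip(offsets, values):
            b.measurement(pid, vid, vocab.HEART_RATE, t0 + _dt.timedelta(seconds=t), v)
        segs = [
            (t, nxt, float(v))
            for t, nxt, v in zip(offsets, list(offsets[1:]) + [proc_s], values)
        ]
        n_events = min(int(rng.integers(1, 3)), spec.n_units - made)
        # first event sometimes < 10 min after the start (window clips)
        starts = sorted(
            int(rng.integers(60, 500)) if (j == 0 and rng.random() < 0.3)
            else int(rng.integers(700 + j * 1500, 1500 + j * 1500))
            for j in range(n_events)
        )
        for t_evt in starts:
            when = t0 + _dt.timedelta(seconds=t_evt)
            did = b.drug(pid, vid, vocab.ATROPINE, _iso_day(when), 0,
                         start_datetime=when.isoformat())
            uid = did
            b.unit(uid, "event_occurrence", pid, anchor=did, visit=vid)
            made += 1
            for tag, lo, hi in (
                ("before", max(0, t_evt - 600), t_evt),
                ("after", t_evt, min(proc_s, t_evt + 600)),
            ):
                stats = _per_second_stats(segs, lo, hi)
                for name, val in stats.items():
                    b.answer(uid, f"hr_{name}_{tag}", val)


def _gen_sc5(b: _Builder, rng: np.random.Generator, spec: ScenarioSpec) -> None:
    """Ventilated procedures with an end-tidal-volume signal and a per-person
    ideal body weight; features: time-weighted mean of mL/kg over the surgery
    and the guideline-compliance indicator (mean below 8 mL/kg)."""
    for i in range(spec.n_units):
        ibw = float(np.round(rng.uniform(45.0, 90.0), 1))
        pid = b.person(ibw=ibw)
        t0 = EPOCH + _dt.timedelta(days=i, hours=10)
        proc_s = int(rng.integers(3600, 3 * 3600))
        t_end = t0 + _dt.timedelta(seconds=proc_s)
        vid = b.visit(pid, VISIT_CONCEPTS["sc5"], t0.isoformat(), t_end.isoformat())
        anchor = b.procedure(pid, vid, vocab.ANESTHESIA_START, t0)
        b.procedure(pid, vid, vocab.ANESTHESIA_END, t_end)
        uid = anchor
        b.unit(uid, "procedure_occurrence", pid, anchor=anchor, visit=vid)
        per_kg = float(np.round(rng.uniform(5.5, 9.5), 2))
        baseline = float(np.round(per_kg * ibw, 1))
        episodes = _plant_episodes(rng, spec, 300, proc_s - 300)
        level = float(np.round(baseline * rng.uniform(0.85, 1.15), 1))
        segs = _truth_segments(proc_s, baseline, episodes, level)
        segs = _emit_signal(b, rng, spec, pid=pid, vid=vid, concept=vocab.TIDAL_VOLUME,
                            t0=t0, segs=segs)
        mean_per_kg = _weighted_mean(
            [(s, e, v / ibw) for s, e, v in segs], 0, proc_s
        )
        b.answer(uid, "tv_per_kg_mean", mean_per_kg)
        b.answer(uid, "tv_guideline_compliant", 1 if mean_per_kg < 8.0 else 0)


def _gen_sc6(b: _Builder, rng: np.random.Generator, spec: ScenarioSpec) -> None:
    """Day-granular hospital stays with drug dispensings; features: number of
    distinct flagged (potentially inappropriate) drugs whose exposure touches
    the 90 days before admission, and the same for the 90 days after
    discharge."""
    for i in range(spec.n_units):
        pid = b.person(year_of_birth=int(rng.integers(1930, 1950)))
        adm = (EPOCH + _dt.timedelta(days=120 + 2 * i)).date()
        disch = adm + _dt.timedelta(days=int(rng.integers(2, 15)))
        vid = b.visit(pid, VISIT_CONCEPTS["sc6"], adm.isoformat(), disch.isoformat())
        b.unit(vid, "visit", pid, visit=vid)
        codes = list(vocab.LAROCHE_CODES)
        rng.shuffle(codes)
        k_before = int(rng.integers(0, spec.max_in_window + 1))
        k_after = int(rng.integers(0, spec.max_in_window + 1))
        before_codes = codes[:k_before]
        after_pool = list(vocab.LAROCHE_CODES)
        rng.shuffle(after_pool)
        after_codes = after_pool[:k_after]
        out_codes = [c for c in codes[k_before:]][: spec.max_out_window]
        for code in before_codes:
            if rng.random() < 0.2:  # exposure crossing the window start
                start = adm - _dt.timedelta(days=90 + int(rng.integers(1, 4)))
                days = int(rng.integers(4, 9))
            else:
                start = adm - _dt.timedelta(days=int(rng.integers(11, 86)))
                days = int(rng.integers(3, 11))
            b.drug(pid, vid, code, start.isoformat(), days)
        for code in after_codes:
            start = disch + _dt.timedelta(days=int(rng.integers(5, 71)))
            b.drug(pid, vid, code, start.isoformat(), int(rng.integers(3, 11)))
        for code in out_codes:  # entirely before the pre-admission window
            start = adm - _dt.timedelta(days=int(rng.integers(120, 200)))
            b.drug(pid, vid, code, start.isoformat(), int(rng.integers(3, 9)))
        for code in vocab.DISTRACTOR_CODES[:2]:  # never flagged, any time
            start = adm - _dt.timedelta(days=int(rng.integers(1, 80)))
            b.drug(pid, vid, code, start.isoformat(), int(rng.integers(3, 9)))
        b.answer(vid, "laroche_count_before", len(before_codes))
        b.answer(vid, "laroche_count_after", len(after_codes))


def _gen_sc7(b: _Builder, rng: np.random.Generator, spec: ScenarioSpec) -> None:
    """Patients on vitamin K antagonists with interacting co-medication and
    daily INR results; features: per patient, the number of
    drug–drug-interaction observation periods containing an INR >= 5
    (potentiation) and containing an INR <= 1.5 (inhibition)."""
    for i in range(spec.n_units):
        pid = b.person(year_of_birth=int(rng.integers(1935, 1960)))
        b.unit(pid, "person", pid)
        base_day = (EPOCH + _dt.timedelta(days=30 + i)).date()
        n_ov = int(rng.integers(0, spec.max_overlaps + 1))
        pot = inh = 0
        excursion_days: list[tuple[_dt.date, float]] = []
        obs_windows: list[tuple[_dt.date, _dt.date]] = []
        for j in range(n_ov):
            s = base_day + _dt.timedelta(days=60 * j)
            vka_code = vocab.VKA_CODES[int(rng.integers(0, len(vocab.VKA_CODES)))]
            partner = vocab.DDI_PARTNER_CODES[
                int(rng.integers(0, len(vocab.DDI_PARTNER_CODES)))
            ]
            vka_days = int(rng.integers(15, 26))
            b.drug(pid, "", vka_code, s.isoformat(), vka_days)
            p_off = int(rng.integers(2, 8))
            p_days = int(rng.integers(4, min(10, vka_days - p_off) + 1))
            b.drug(pid, "", partner, (s + _dt.timedelta(days=p_off)).isoformat(), p_days)
            ov_start = s + _dt.timedelta(days=p_off)
            ov_end = ov_start + _dt.timedelta(days=p_days)
            obs = (ov_start + DAY, ov_end + 4 * DAY)  # the printed DDI rule
            obs_windows.append(obs)
            obs_len = (obs[1] - obs[0]).days
            free_days = [obs[0] + _dt.timedelta(days=k) for k in range(obs_len)]
            if rng.random() < 0.5:
                day = free_days.pop(int(rng.integers(0, len(free_days))))
                excursion_days.append((day, vocab.INR_HIGH + 1.0))
                pot += 1
            if rng.random() < 0.3 and free_days:
                day = free_days.pop(int(rng.integers(0, len(free_days))))
                excursion_days.append((day, vocab.INR_LOW - 0.3))
                inh += 1
        # distractors: an isolated VKA course with no partner, and an INR
        # excursion far from every observation window
        lone = base_day + _dt.timedelta(days=200)
        b.drug(pid, "", vocab.VKA_CODES[0], lone.isoformat(), 10)
        if rng.random() < 0.4:
            excursion_days.append((base_day - _dt.timedelta(days=20), vocab.INR_HIGH + 0.5))
        # daily INR from 30 days before the first course to the end
        span_start = base_day - _dt.timedelta(days=30)
        span_end = lone + _dt.timedelta(days=15)
        excursions = dict(excursion_days)
        d = span_start
        while d < span_end:
            value = excursions.get(d, 2.5)
            b.measurement(pid, "", vocab.INR,
                          _dt.datetime.combine(d, _dt.time(8)), value)
            d += DAY
        b.answer(pid, "vka_potentiation_count", pot)
        b.answer(pid, "vka_inhibition_count", inh)


def _gen_sc8(b: _Builder, rng: np.random.Generator, spec: ScenarioSpec) -> None:
    """Suspected-COPD screening: patients over 40 with bronchodilators, three
    antibiotic courses for respiratory infection, or nicotinic substitutes.
    Features: the suspect indicator for every patient and, for suspects, the
    count of COPD-specific administrations in the year following the first
    such exposure plus a functional-respiratory-exploration indicator."""
    for i in range(spec.n_units):
        age = int(rng.integers(30, 90))
        pid = b.person(year_of_birth=EPOCH.year - age)
        b.unit(pid, "person", pid)
        anchor_day = (EPOCH + _dt.timedelta(days=10 + i)).date()
        n_bronch = int(rng.integers(0, 3))
        n_abx = int(rng.integers(0, 5))
        n_nic = int(rng.integers(0, 2))
        qualifies = n_bronch >= 1 or n_abx >= 3 or n_nic >= 1
        suspect = age > 40 and qualifies
        planted: list[tuple[int, str]] = []  # (day offset from anchor, code)
        counts = (
            (n_bronch, vocab.BRONCHODILATOR_CODES),
            (n_abx, vocab.RESP_ANTIBIOTIC_CODES),
            (n_nic, vocab.NICOTINIC_CODES),
        )
        n_total = n_bronch + n_abx + n_nic
        # distinct administration days: one row per administration
        offs = iter(
            sorted(rng.choice(np.arange(1, 300), size=n_total, replace=False).tolist())
        ) if n_total else iter(())
        for n, pool in counts:
            for _ in range(n):
                code = pool[int(rng.integers(0, len(pool)))]
                planted.append((next(offs), code))
        if planted:
            planted[0] = (0, planted[0][1])  # the anchor exposure itself
        planted.sort()
        in_window = len(planted)
        # late exposures beyond the one-year window never count; for a
        # non-qualifying patient they must not tip the whole-history rule
        # either, so they stay antibiotic courses and are only planted while
        # the three-course criterion stays out of reach
        n_late = int(rng.integers(0, 2))
        if not qualifies and n_abx >= 2:
            n_late = 0
        late_pool = (
            vocab.COPD_SPECIFIC_CODES if qualifies else vocab.RESP_ANTIBIOTIC_CODES
        )
        for _ in range(n_late):
            code = late_pool[int(rng.integers(0, len(late_pool)))]
            planted.append((int(rng.integers(400, 500)), code))
        for off, code in planted:
            day = anchor_day + _dt.timedelta(days=off)
            b.drug(pid, "", code, day.isoformat(), 1)
        fre = 0
        if suspect and rng.random() < 0.6:
            day = anchor_day + _dt.timedelta(days=int(rng.integers(30, 360)))
            b.procedure(pid, "", vocab.SPIROMETRY,
                        _dt.datetime.combine(day, _dt.time(9)))
            fre = 1
        elif rng.random() < 0.2:  # exploration outside the window: no credit
            day = anchor_day + _dt.timedelta(days=int(rng.integers(400, 450)))
            b.procedure(pid, "", vocab.SPIROMETRY,
                        _dt.datetime.combine(day, _dt.time(9)))
        b.answer(pid, "copd_suspect", 1 if suspect else 0)
        if suspect:
            b.answer(pid, "copd_drug_count_1y", in_window)
            b.answer(pid, "fre_done_1y", fre)


_GENERATORS = {
    "sc1": _gen_sc1,
    "sc2": lambda b, r, s: _gen_anesthesia_case(b, r, s, "sc2"),
    "sc3": lambda b, r, s: _gen_anesthesia_case(b, r, s, "sc3"),
    "sc4": _gen_sc4,
    "sc5": _gen_sc5,
    "sc6": _gen_sc6,
    "sc7": _gen_sc7,
    "sc8": _gen_sc8,
}


def generate(spec: ScenarioSpec, out_dir=None) -> Bundle:
    """Generate the raw table bundle and answer key for a scenario.

    The same spec (including seed) produces byte-identical files.  With
    ``scenario="mixed"`` all eight scenarios are generated into one bundle
    with id prefixes keeping their populations apart.
    """
    if spec.scenario == "mixed":
        builders = []
        for k, sc in enumerate(SCENARIOS):
            sub = dataclasses.replace(spec, scenario=sc, seed=spec.seed + k)
            b = _Builder(prefix=f"{sc}-")
            _GENERATORS[sc](b, np.random.default_rng(sub.seed), sub)
            builders.append(b.bundle(sc))
        tables = {
            name: pd.concat(
                [bb.tables[name] for bb in builders], ignore_index=True
            )
            for name in TABLE_COLUMNS
        }
        units = {k: v for bb in builders for k, v in bb.units.items()}
        key = pd.concat([bb.answer_key for bb in builders], ignore_index=True)
        bundle = Bundle("mixed", tables, units, key)
    else:
        b = _Builder()
        _GENERATORS[spec.scenario](b, np.random.default_rng(spec.seed), spec)
        bundle = b.bundle(spec.scenario)
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


# ---------------------------------------------------------------------------
# hand-written worked fixture (one stay, two flagged drugs)
# ---------------------------------------------------------------------------


def generate_worked_sc6_fixture() -> tuple[Bundle, dict[str, object]]:
    """Miniature hand-written bundle for the worked pre-admission-medication
    example, with the expected intermediate track after each of the eight
    pipeline steps.

    One hospital stay (admitted 2021-03-10, discharged 2021-03-15), two
    flagged drugs: drug A exposed twice (once long before the 90-day window,
    once inside it) and drug B exposed across the admission date, plus one
    unflagged distractor.  The final feature — distinct flagged drugs in the
    90 days before admission — is 2 by construction.
    """
    b = _Builder()
    pid = b.person(year_of_birth=1940)
    vid = b.visit(pid, VISIT_CONCEPTS["sc6"], "2021-03-10", "2021-03-15")
    b.unit(vid, "visit", pid, visit=vid)
    drug_a, drug_b = vocab.LAROCHE_CODES[0], vocab.LAROCHE_CODES[1]
    b.drug(pid, vid, drug_a, "2020-09-01", 5)   # far outside the window
    b.drug(pid, vid, drug_a, "2021-02-01", 10)  # inside the window
    b.drug(pid, vid, drug_b, "2021-03-05", 10)  # crosses the admission date
    b.drug(pid, vid, vocab.DISTRACTOR_CODES[0], "2021-02-15", 5)  # not flagged
    b.answer(vid, "laroche_count_before", 2)
    bundle = b.bundle("sc6")

    def day(s: str) -> _dt.datetime:
        return _dt.datetime.fromisoformat(s)

    def track(concept: str, recs: list[tuple[str, str, object]]) -> IntervalTrack:
        return IntervalTrack(
            vid, concept,
            [IntervalRecord(Interval(day(s), day(e)), v) for s, e, v in recs],
        )

    expected: dict[str, object] = {
        "step1_stay": track("hospital_stay", [("2021-03-10", "2021-03-16", 1)]),
        "step2_window": track("90_days_before", [("2020-12-10", "2021-03-10", 1)]),
        "step3_drug_a": track(
            "laroche_exposure",
            [("2020-09-01", "2020-09-06", drug_a), ("2021-02-01", "2021-02-11", drug_a)],
        ),
        "step4_drug_b": track(
            "laroche_exposure", [("2021-03-05", "2021-03-15", drug_b)]
        ),
        "step5_a_masked": track(
            "laroche_exposure/90_days_before", [("2021-02-01", "2021-02-11", drug_a)]
        ),
        "step6_b_masked": track(
            "laroche_exposure/90_days_before", [("2021-03-05", "2021-03-10", drug_b)]
        ),
        "step7_union": track(
            "laroche_in_window",
            [("2021-02-01", "2021-02-11", drug_a), ("2021-03-05", "2021-03-10", drug_b)],
        ),
        "step8_count_distinct": 2,
    }
    return bundle, expected
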