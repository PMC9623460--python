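"""Reference feature-extraction pipelines for the eight bundled study cases.

Each case is a declarative configuration (``cases/<case>.yaml`` — concept
sets, milestone priorities, thresholds, windows, and the feature definitions
with their seven documentation items) plus a pipeline function that composes
**only** the track-definition and track-aggregation operations of this
package: selection, interval construction, window shifting, milestone
selection, resampling, thresholding, interval algebra, and the closed
catalogue of extraction methods.  No case-specific arithmetic lives here;
everything a case computes is expressible as those operations, which is what
makes the pipelines reproducible from their definitions.

The cases:

* sc1 — weighted average of PaO2 over the first 24 h of eligible ICU stays;
* sc2 — seconds of mean arterial pressure below 90 % of a pre-incision
  reference during heavy surgery;
* sc3 — seconds of systolic pressure below 80 % of the arrival-to-induction
  reference during cesarean section (induction documented by up to four
  concepts under an expert priority rule);
* sc4 — median/min/max heart rate in the 10 minutes before and after each
  atropine administration (the administration is the statistical unit);
* sc5 — mean end-tidal volume per kg ideal body weight during surgery and
  the below-8 mL/kg guideline-compliance indicator;
* sc6 — distinct flagged (potentially inappropriate) drugs in the 90 days
  before admission and after discharge of each hospital stay;
* sc7 — per patient, counts of drug–drug-interaction observation periods
  with an INR >= 5 (potentiation) and <= 1.5 (inhibition);
* sc8 — the suspected-COPD indicator, and for suspects the count of
  COPD-specific administrations plus the respiratory-exploration indicator
  in the year following the first such exposure.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import vocab
from .aggregation import FeatureDefinition, run_definition, threshold_feature
from .core import (
    Exclusion,
    Feature,
    Interval,
    IntervalTrack,
    SignalTrack,
    StatisticalUnit,
    promote_date,
)
from .definition import (
    ConceptSet,
    ConceptSetMember,
    MilestoneRule,
    UnitMap,
    WindowSpec,
    build_period,
    count_condition_track,
    ddi_observation_period,
    exposure_intervals,
    filter_records,
    intersect,
    interval_from_fields,
    reference_constant,
    resample,
    select_events,
    select_milestone,
    shift_window,
    threshold_episodes,
    transform_signal,
    union,
)
from .errors import (
    ConfigurationError,
    InputFormatError,
    MalformedTrackError,
    MissingMilestoneError,
)
from .simulate import Bundle
from .store import write_features, write_manifest, write_tracks

__all__ = ["CASE_IDS", "CaseResult", "load_case_config", "run_case", "sc6_worked_steps"]

CASE_IDS = ("sc1", "sc2", "sc3", "sc4", "sc5", "sc6", "sc7", "sc8")

DAY = _dt.timedelta(days=1)


def load_case_config(case_id: str) -> dict:
    """Load the shipped configuration of one study case."""
    if case_id not in CASE_IDS:
        raise ConfigurationError(f"unknown case {case_id!r}")
    text = resources.files("trackfeat").joinpath(f"cases/{case_id}.yaml").read_text()
    return yaml.safe_load(text)


@dataclass
class CaseResult:
    """Everything a case run produced: the unit registry, every intermediate
    track (the reproducibility record), the periods of interest, the features
    and per-unit exclusions, and the definitions that were executed."""

    case_id: str
    units: dict[str, StatisticalUnit]
    tracks: dict[str, dict[str, object]]
    periods: dict[str, dict[str, Interval]]
    features: list[Feature]
    exclusions: list[Exclusion]
    definitions: list[FeatureDefinition]

    def features_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "unit_id": f.unit_id,
                    "feature_concept": f.feature_concept,
                    "value": f.value,
                    "definition_id": f.definition_id,
                }
                for f in self.features
            ],
            columns=["unit_id", "feature_concept", "value", "definition_id"],
        )

    def write(self, out_dir, *, write_intermediates: bool = True) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        all_tracks = [
            t
            for name in sorted(self.tracks)
            for _, t in sorted(self.tracks[name].items())
        ]
        if write_intermediates:
            write_tracks(all_tracks, out / "TRACK.csv", units=self.units)
        write_features(self.features, out / "FEATURE.csv", units=self.units)
        pd.DataFrame(
            [{"unit_id": e.unit_id, "reason": e.reason} for e in self.exclusions],
            columns=["unit_id", "reason"],
        ).to_csv(out / "exclusions.csv", index=False, lineterminator="\n")
        write_manifest(
            out / "manifest.json", units=self.units, definitions=self.definitions,
            extra={"case_id": self.case_id},
        )


# ---------------------------------------------------------------------------
# shared glue (table access, unit registries, signal assembly)
# ---------------------------------------------------------------------------


def _dt_of(s: str) -> _dt.datetime:
    return promote_date(s)


def _empty(unit_id: str, concept: str) -> IntervalTrack:
    return IntervalTrack(unit_id, concept)


def _concept_set(set_id: str, vocabulary: str, codes, *, target: str | None = None,
                 prefix: bool = False) -> ConceptSet:
    return ConceptSet(
        set_id,
        [ConceptSetMember(vocabulary, c, is_prefix=prefix, target_concept=target)
         for c in codes],
    )


def _select_visits(bundle: Bundle, visit_concept: str) -> pd.DataFrame:
    df = bundle.tables.get("visit_occurrence", pd.DataFrame())
    if df.empty:
        return df
    return df[df["visit_concept_id"] == visit_concept]


def _visit_units(visits: pd.DataFrame) -> dict[str, StatisticalUnit]:
    return {
        str(r["visit_occurrence_id"]): StatisticalUnit(
            str(r["visit_occurrence_id"]), "visit", str(r["person_id"]),
            visit_occurrence_id=str(r["visit_occurrence_id"]),
        )
        for _, r in visits.iterrows()
    }


def _person_units(bundle: Bundle) -> dict[str, StatisticalUnit]:
    df = bundle.tables.get("person", pd.DataFrame())
    return {
        str(r["person_id"]): StatisticalUnit(str(r["person_id"]), "person", str(r["person_id"]))
        for _, r in df.iterrows()
    }


def _procedure_units(
    bundle: Bundle, visits: pd.DataFrame, start_concept: str
) -> tuple[dict[str, StatisticalUnit], dict[str, str]]:
    """One procedure-level unit per visit, identified by the procedure row
    documenting the procedure start; returns (units, visit_id -> unit_id)."""
    proc = bundle.tables.get("procedure_occurrence", pd.DataFrame())
    units: dict[str, StatisticalUnit] = {}
    visit_to_unit: dict[str, str] = {}
    if proc.empty or visits.empty:
        return units, visit_to_unit
    wanted = set(visits["visit_occurrence_id"].astype(str))
    rows = proc[proc["procedure_concept_id"] == start_concept]
    rows = rows.sort_values(["procedure_datetime", "procedure_occurrence_id"])
    for _, r in rows.iterrows():
        vid = str(r["visit_occurrence_id"])
        if vid not in wanted or vid in visit_to_unit:
            continue
        uid = str(r["procedure_occurrence_id"])
        units[uid] = StatisticalUnit(
            uid, "procedure_occurrence", str(r["person_id"]),
            anchor_id=uid, visit_occurrence_id=vid,
        )
        visit_to_unit[vid] = uid
    return units, visit_to_unit


def _signals_by_visit(
    bundle: Bundle,
    concept: str,
    domains: dict[str, Interval],
    visit_to_unit: dict[str, str],
    *,
    step_s: int,
    max_gap_s: int,
    track_concept: str,
) -> dict[str, SignalTrack]:
    """Resample one measurement concept per unit over its domain."""
    meas = bundle.tables.get("measurement", pd.DataFrame())
    out: dict[str, SignalTrack] = {}
    if meas.empty:
        return out
    rows = meas[meas["measurement_concept_id"] == concept]
    for vid, grp in rows.groupby("visit_occurrence_id"):
        uid = visit_to_unit.get(str(vid), str(vid))
        if uid not in domains:
            continue
        samples = [
            (_dt_of(t), float(v))
            for t, v in zip(grp["measurement_datetime"], grp["value_as_number"])
        ]
        out[uid] = resample(
            samples, step=step_s, max_gap=max_gap_s, domain=domains[uid],
            unit_id=uid, track_concept=track_concept,
        )
    return out


def _milestone_times(
    events: dict[str, IntervalTrack],
    rule: MilestoneRule,
    units,
    exclusions: list[Exclusion],
    what: str,
) -> dict[str, _dt.datetime]:
    out: dict[str, _dt.datetime] = {}
    for uid in sorted(units):
        track = events.get(uid)
        if track is None or track.is_empty:
            exclusions.append(Exclusion(uid, f"missing {what} milestone"))
            continue
        try:
            out[uid] = select_milestone(track, rule)
        except MissingMilestoneError:
            exclusions.append(Exclusion(uid, f"missing {what} milestone"))
    return out


def _defns(cfg: dict) -> list[FeatureDefinition]:
    return [FeatureDefinition.model_validate(d) for d in cfg.get("definitions", [])]


def _run_defns(
    defns, tracks, periods
) -> tuple[list[Feature], list[Exclusion]]:
    features: list[Feature] = []
    exclusions: list[Exclusion] = []
    for d in defns:
        f, e = run_definition(d, tracks, periods)
        features.extend(f)
        exclusions.extend(e)
    return features, exclusions


# ---------------------------------------------------------------------------
# case pipelines
# ---------------------------------------------------------------------------


def _run_sc1(bundle: Bundle, cfg: dict) -> CaseResult:
    visits = _select_visits(bundle, cfg["visit_concept"])
    flag = cfg.get("eligibility_column")
    if flag and not visits.empty and flag in visits.columns:
        # inclusion criterion (ventilated septic shock) supplied as a flag
        visits = visits[visits[flag] == "1"]
    units = _visit_units(visits)
    exclusions: list[Exclusion] = []
    periods_first = {}
    for _, r in visits.iterrows():
        vid = str(r["visit_occurrence_id"])
        start = _dt_of(r["visit_start_date"])
        periods_first[vid] = build_period(
            start, start, offset_end=int(cfg["period_hours"]) * 3600
        )
    signals = _signals_by_visit(
        bundle, cfg["signal_concept"], periods_first, {},
        step_s=cfg["resample"]["step_s"], max_gap_s=cfg["resample"]["max_gap_s"],
        track_concept="pao2",
    )
    tracks = {"pao2": signals}
    periods = {"first_24h": periods_first}
    defns = _defns(cfg)
    features, excl = _run_defns(defns, tracks, periods)
    return CaseResult("sc1", units, tracks, periods, features, exclusions + excl, defns)


def _run_hypotension(bundle: Bundle, cfg: dict, case_id: str) -> CaseResult:
    visits = _select_visits(bundle, cfg["visit_concept"])
    start_rule = MilestoneRule(tuple(cfg["milestones"]["period_start"]))
    units, visit_to_unit = _procedure_units(
        bundle, visits, cfg["anchor_concept"]
    )
    umap = UnitMap.by_mapping(units, "visit_occurrence_id", visit_to_unit)
    all_concepts = sorted(
        set(
            cfg["milestones"]["period_start"]
            + cfg["milestones"]["period_end"]
            + cfg["milestones"]["baseline_start"]
            + cfg["milestones"]["baseline_end"]
        )
    )
    events, _ = select_events(
        bundle.tables["procedure_occurrence"],
        _concept_set("milestones", vocab.LOCAL, all_concepts),
        umap,
        code_column="procedure_concept_id",
        time_column="procedure_datetime",
        vocabulary=vocab.LOCAL,
        track_concept="anesthesia_milestones",
    )
    exclusions: list[Exclusion] = []
    t_start = _milestone_times(events, start_rule, units, exclusions, "period start")
    t_end = _milestone_times(
        events, MilestoneRule(tuple(cfg["milestones"]["period_end"])),
        t_start, exclusions, "period end",
    )
    t_b0 = _milestone_times(
        events, MilestoneRule(tuple(cfg["milestones"]["baseline_start"])),
        t_end, exclusions, "baseline start",
    )
    t_b1 = _milestone_times(
        events, MilestoneRule(tuple(cfg["milestones"]["baseline_end"])),
        t_b0, exclusions, "baseline end",
    )
    anesthesia_period: dict[str, Interval] = {}
    baseline_period: dict[str, Interval] = {}
    for uid in sorted(t_b1):
        try:
            anesthesia_period[uid] = build_period(t_start[uid], t_end[uid])
            baseline_period[uid] = build_period(t_b0[uid], t_b1[uid])
        except MalformedTrackError:
            exclusions.append(Exclusion(uid, "inverted period of interest"))
    domains = {
        uid: build_period(t_b0[uid], t_end[uid]) for uid in anesthesia_period
    }
    signals = _signals_by_visit(
        bundle, cfg["signal_concept"], domains, visit_to_unit,
        step_s=cfg["resample"]["step_s"], max_gap_s=cfg["resample"]["max_gap_s"],
        track_concept=cfg["signal_track"],
    )
    episodes: dict[str, IntervalTrack] = {}
    for uid in sorted(anesthesia_period):
        signal = signals.get(uid)
        if signal is None or not signal.is_defined_anywhere:
            exclusions.append(Exclusion(uid, "signal undefined"))
            continue
        ref = reference_constant(signal, baseline_period[uid])
        if ref is None:
            exclusions.append(Exclusion(uid, "reference undefined over baseline period"))
            continue
        episodes[uid] = threshold_episodes(
            signal,
            cfg["threshold"]["comparator"],
            float(cfg["threshold"]["fraction"]),
            reference=ref,
            relative=True,
            min_duration=int(cfg["threshold"].get("min_duration_s", 0)),
            merge_gap=int(cfg["threshold"].get("merge_gap_s", 0)),
            track_concept="hypotension_episodes",
        )
    tracks = {cfg["signal_track"]: signals, "hypotension_episodes": episodes}
    periods = {"anesthesia_period": {u: anesthesia_period[u] for u in episodes}}
    defns = _defns(cfg)
    features, excl = _run_defns(defns, tracks, periods)
    return CaseResult(case_id, units, tracks, periods, features, exclusions + excl, defns)


def _run_sc4(bundle: Bundle, cfg: dict) -> CaseResult:
    visits = _select_visits(bundle, cfg["visit_concept"])
    drug = bundle.tables.get("drug_exposure", pd.DataFrame())
    units: dict[str, StatisticalUnit] = {}
    event_time: dict[str, _dt.datetime] = {}
    unit_visit: dict[str, str] = {}
    if not drug.empty and not visits.empty:
        wanted = set(visits["visit_occurrence_id"].astype(str))
        rows = drug[drug["drug_concept_id"] == cfg["event_drug"]]
        for _, r in rows.iterrows():
            vid = str(r["visit_occurrence_id"])
            if vid not in wanted:
                continue
            uid = str(r["drug_exposure_id"])
            units[uid] = StatisticalUnit(
                uid, "event_occurrence", str(r["person_id"]),
                anchor_id=uid, visit_occurrence_id=vid,
            )
            event_time[uid] = _dt_of(r["drug_exposure_start_datetime"])
            unit_visit[uid] = vid
    domains = {
        str(r["visit_occurrence_id"]): Interval(
            _dt_of(r["visit_start_date"]), _dt_of(r["visit_end_date"])
        )
        for _, r in visits.iterrows()
    }
    visit_signals = _signals_by_visit(
        bundle, cfg["signal_concept"], domains, {},
        step_s=cfg["resample"]["step_s"], max_gap_s=cfg["resample"]["max_gap_s"],
        track_concept="heart_rate",
    )
    minutes = int(cfg["window_minutes"]) * 60
    signals: dict[str, SignalTrack] = {}
    before: dict[str, Interval] = {}
    after: dict[str, Interval] = {}
    exclusions: list[Exclusion] = []
    for uid in sorted(units):
        sig = visit_signals.get(unit_visit[uid])
        if sig is None:
            exclusions.append(Exclusion(uid, "signal undefined"))
            continue
        # the visit's signal, rebound to the event-level unit
        signals[uid] = SignalTrack(uid, sig.track_concept, list(sig.segments), sig.domain)
        t = event_time[uid]
        before[uid] = build_period(t, t, offset_start=-minutes)
        after[uid] = build_period(t, t, offset_end=minutes)
    tracks = {"heart_rate": signals}
    periods = {"before_window": before, "after_window": after}
    defns = _defns(cfg)
    features, excl = _run_defns(defns, tracks, periods)
    return CaseResult("sc4", units, tracks, periods, features, exclusions + excl, defns)


def _run_sc5(bundle: Bundle, cfg: dict) -> CaseResult:
    visits = _select_visits(bundle, cfg["visit_concept"])
    units, visit_to_unit = _procedure_units(bundle, visits, cfg["anchor_concept"])
    umap = UnitMap.by_mapping(units, "visit_occurrence_id", visit_to_unit)
    events, _ = select_events(
        bundle.tables["procedure_occurrence"],
        _concept_set("milestones", vocab.LOCAL,
                     [cfg["anchor_concept"], cfg["end_concept"]]),
        umap,
        code_column="procedure_concept_id",
        time_column="procedure_datetime",
        vocabulary=vocab.LOCAL,
        track_concept="surgery_milestones",
    )
    exclusions: list[Exclusion] = []
    t_start = _milestone_times(
        events, MilestoneRule((cfg["anchor_concept"],)), units, exclusions, "start")
    t_end = _milestone_times(
        events, MilestoneRule((cfg["end_concept"],)), t_start, exclusions, "end")
    surgery: dict[str, Interval] = {}
    for uid in sorted(t_end):
        try:
            surgery[uid] = build_period(t_start[uid], t_end[uid])
        except MalformedTrackError:
            exclusions.append(Exclusion(uid, "inverted surgery period"))
    person = bundle.tables.get("person", pd.DataFrame())
    ibw = {
        str(r["person_id"]): float(r["ideal_body_weight"])
        for _, r in person.iterrows()
        if str(r.get("ideal_body_weight", "")).strip()
    }
    raw_signals = _signals_by_visit(
        bundle, cfg["signal_concept"], surgery, visit_to_unit,
        step_s=cfg["resample"]["step_s"], max_gap_s=cfg["resample"]["max_gap_s"],
        track_concept="tidal_volume",
    )
    per_kg: dict[str, SignalTrack] = {}
    for uid in sorted(surgery):
        sig = raw_signals.get(uid)
        if sig is None or not sig.is_defined_anywhere:
            exclusions.append(Exclusion(uid, "signal undefined"))
            continue
        weight = ibw.get(units[uid].person_id)
        if not weight:
            exclusions.append(Exclusion(uid, "missing or zero ideal body weight"))
            continue
        per_kg[uid] = transform_signal(sig, weight, "divide")
    tracks = {"tidal_volume": raw_signals, "tidal_volume_per_kg": per_kg}
    periods = {"surgery_period": {u: surgery[u] for u in per_kg}}
    defns = _defns(cfg)
    features, excl = _run_defns(defns, tracks, periods)
    post = cfg.get("post_threshold")
    if post:
        derived = [
            threshold_feature(
                f, post["comparator"], float(post["threshold"]),
                feature_concept=post["feature_concept"],
                definition_id=post.get("definition_id"),
            )
            for f in features
            if f.feature_concept == post["from_feature"]
        ]
        features = features + derived
    return CaseResult("sc5", units, tracks, periods, features, exclusions + excl, defns)


def _run_sc6(bundle: Bundle, cfg: dict) -> CaseResult:
    visits = _select_visits(bundle, cfg["visit_concept"])
    units = _visit_units(visits)
    umap = UnitMap.by_column(units, "visit_occurrence_id")
    stays, _ = interval_from_fields(
        visits, umap,
        start_field="visit_start_date", end_field="visit_end_date",
        track_concept="hospital_stay",
    )
    win_days = int(cfg["window_days"])
    before = {
        u: shift_window(t, WindowSpec("start", -win_days * DAY, _dt.timedelta(0)),
                        track_concept="90_days_before")
        for u, t in stays.items()
    }
    after = {
        u: shift_window(t, WindowSpec("end", _dt.timedelta(0), win_days * DAY),
                        track_concept="90_days_after")
        for u, t in stays.items()
    }
    cs = _concept_set(cfg["concept_set"]["set_id"], vocab.ATC, cfg["concept_set"]["codes"])
    expo, _ = exposure_intervals(
        bundle.tables.get("drug_exposure", pd.DataFrame(columns=["person_id"])),
        umap,
        concept_set=cs, code_column="drug_concept_id", vocabulary=vocab.ATC,
        track_concept="laroche_exposure",
    )
    masked_before = {
        u: intersect(expo.get(u, _empty(u, "laroche_exposure")), before[u],
                     track_concept="laroche_before")
        for u in sorted(units) if u in before
    }
    masked_after = {
        u: intersect(expo.get(u, _empty(u, "laroche_exposure")), after[u],
                     track_concept="laroche_after")
        for u in sorted(units) if u in after
    }
    periods = {
        "before_window": {u: t.records[0].interval for u, t in before.items() if t.records},
        "after_window": {u: t.records[0].interval for u, t in after.items() if t.records},
    }
    tracks = {
        "hospital_stay": stays,
        "90_days_before": before,
        "90_days_after": after,
        "laroche_exposure": expo,
        "laroche_before": masked_before,
        "laroche_after": masked_after,
    }
    defns = _defns(cfg)
    features, excl = _run_defns(defns, tracks, periods)
    return CaseResult("sc6", units, tracks, periods, features, excl, defns)


def _run_sc7(bundle: Bundle, cfg: dict) -> CaseResult:
    units = _person_units(bundle)
    umap = UnitMap.by_person(units)
    drug = bundle.tables.get("drug_exposure", pd.DataFrame(columns=["person_id"]))
    vka_cs = _concept_set("vka", vocab.ATC, cfg["vka_codes"], target=cfg["vka_category"])
    ddi_cs = _concept_set(
        "ddi_partner", vocab.ATC, cfg["partner_codes"], target=cfg["partner_category"]
    )
    vka, _ = exposure_intervals(
        drug, umap, concept_set=vka_cs, code_column="drug_concept_id",
        vocabulary=vocab.ATC, track_concept="vka_exposure",
    )
    partner, _ = exposure_intervals(
        drug, umap, concept_set=ddi_cs, code_column="drug_concept_id",
        vocabulary=vocab.ATC, track_concept="ddi_partner_exposure",
    )
    obs: dict[str, IntervalTrack] = {}
    for uid in sorted(units):
        a = vka.get(uid)
        b = partner.get(uid)
        if a is None or b is None:
            obs[uid] = _empty(uid, "ddi_observation")
            continue
        obs[uid] = ddi_observation_period(
            a, b,
            start_lag=int(cfg["start_lag_days"]) * DAY,
            end_lag=int(cfg["end_lag_days"]) * DAY,
        )
    inr, _ = select_events(
        bundle.tables.get("measurement", pd.DataFrame(columns=["person_id"])),
        _concept_set("inr", vocab.LOCAL, [cfg["lab_concept"]]),
        umap,
        code_column="measurement_concept_id",
        time_column="measurement_datetime",
        vocabulary=vocab.LOCAL,
        track_concept="inr_values",
        value_column="value_as_number",
    )
    pot: dict[str, IntervalTrack] = {}
    inh: dict[str, IntervalTrack] = {}
    for uid in sorted(units):
        values = inr.get(uid, _empty(uid, "inr_values"))
        hi = filter_records(values, ">=", float(cfg["inr_high"]),
                            track_concept="inr_high", keep_value=1)
        lo = filter_records(values, "<=", float(cfg["inr_low"]),
                            track_concept="inr_low", keep_value=1)
        pot[uid] = count_condition_track(hi, 1, obs[uid], track_concept="vka_potentiation")
        inh[uid] = count_condition_track(lo, 1, obs[uid], track_concept="vka_inhibition")
    study = Interval(_dt_of(cfg["study_period"][0]), _dt_of(cfg["study_period"][1]))
    tracks = {
        "vka_exposure": vka,
        "ddi_partner_exposure": partner,
        "ddi_observation": obs,
        "vka_potentiation": pot,
        "vka_inhibition": inh,
    }
    periods = {"study_period": {u: study for u in units}}
    defns = _defns(cfg)
    features, excl = _run_defns(defns, tracks, periods)
    return CaseResult("sc7", units, tracks, periods, features, excl, defns)


def _run_sc8(bundle: Bundle, cfg: dict) -> CaseResult:
    units = _person_units(bundle)
    umap = UnitMap.by_person(units)
    drug = bundle.tables.get("drug_exposure", pd.DataFrame(columns=["person_id"]))
    study = Interval(_dt_of(cfg["study_period"][0]), _dt_of(cfg["study_period"][1]))
    classes = {}
    for name, spec in cfg["drug_classes"].items():
        cs = _concept_set(name, vocab.ATC, spec["codes"])
        events, _ = select_events(
            drug, cs,
            umap,
            code_column="drug_concept_id",
            time_column="drug_exposure_start_date",
            vocabulary=vocab.ATC,
            track_concept=f"{name}_administrations",
        )
        classes[name] = (events, int(spec["min_count"]))
    person = bundle.tables.get("person", pd.DataFrame())
    # inclusion criterion: age above the configured cutoff at the reference year
    ref_year = int(cfg["age_reference_year"])
    age_ok = {
        str(r["person_id"]): (ref_year - int(r["year_of_birth"])) > int(cfg["age_over"])
        for _, r in person.iterrows()
    }
    qualifying: dict[str, IntervalTrack] = {}
    copd_events: dict[str, IntervalTrack] = {}
    for uid in sorted(units):
        met = _empty(uid, "copd_rule_met")
        all_events = _empty(uid, "copd_administrations")
        for name, (events, min_count) in classes.items():
            track = events.get(uid, _empty(uid, f"{name}_administrations"))
            met = union(met, count_condition_track(track, min_count, study),
                        track_concept="copd_rule_met")
            all_events = union(all_events, track, track_concept="copd_administrations")
        copd_events[uid] = all_events
        qualifying[uid] = met if age_ok.get(uid, False) else _empty(uid, "copd_rule_met")
    tracks: dict[str, dict[str, object]] = {
        "copd_rule_met": qualifying,
        "copd_administrations": copd_events,
    }
    periods: dict[str, dict[str, Interval]] = {"study_period": {u: study for u in units}}
    defns = _defns(cfg)
    suspect_defn = next(d for d in defns if d.feature_concept == cfg["suspect_feature"])
    features, excl = run_definition(suspect_defn, tracks, periods)
    suspects = sorted(
        f.unit_id for f in features if f.value_number == 1.0
    )
    exclusions = list(excl)
    follow: dict[str, Interval] = {}
    for uid in suspects:
        try:
            anchor = select_milestone(
                copd_events[uid], MilestoneRule(("*",), "first")
            )
        except MissingMilestoneError:
            exclusions.append(Exclusion(uid, "no anchoring exposure"))
            continue
        follow[uid] = build_period(
            anchor, anchor, offset_end=int(cfg["follow_days"]) * 24 * 3600
        )
    fre, _ = select_events(
        bundle.tables.get("procedure_occurrence", pd.DataFrame(columns=["person_id"])),
        _concept_set("fre", vocab.LOCAL, [cfg["fre_concept"]]),
        umap,
        code_column="procedure_concept_id",
        time_column="procedure_datetime",
        vocabulary=vocab.LOCAL,
        track_concept="fre_events",
    )
    tracks["fre_events"] = {u: fre.get(u, _empty(u, "fre_events")) for u in suspects}
    periods["follow_year"] = follow
    for d in defns:
        if d is suspect_defn:
            continue
        f, e = run_definition(d, tracks, periods)
        features.extend(f)
        exclusions.extend(e)
    return CaseResult("sc8", units, tracks, periods, features, exclusions, defns)


_RUNNERS = {
    "sc1": _run_sc1,
    "sc2": lambda b, c: _run_hypotension(b, c, "sc2"),
    "sc3": lambda b, c: _run_hypotension(b, c, "sc3"),
    "sc4": _run_sc4,
    "sc5": _run_sc5,
    "sc6": _run_sc6,
    "sc7": _run_sc7,
    "sc8": _run_sc8,
}


def run_case(
    case_id: str,
    bundle: "Bundle | str | Path",
    out_dir=None,
    *,
    write_intermediates: bool = True,
) -> CaseResult:
    """Execute one study-case pipeline on a raw table bundle.

    ``bundle`` is a :class:`~trackfeat.simulate.Bundle` or a directory of raw
    CSV tables.  Every intermediate track is kept on the result (and
    persisted when ``out_dir`` is given) — the pipeline steps, not only the
    final features, are part of the reproducibility record.
    """
    cfg = load_case_config(case_id)
    if not isinstance(bundle, Bundle):
        bundle = Bundle.read(bundle, scenario=case_id)
    missing = [t for t in cfg.get("requires", []) if t not in bundle.tables]
    if missing:
        raise InputFormatError(
            f"case {case_id} requires tables {cfg.get('requires')}; missing {missing}"
        )
    result = _RUNNERS[case_id](bundle, cfg)
    if out_dir is not None:
        result.write(out_dir, write_intermediates=write_intermediates)
    return result


def sc6_worked_steps(bundle: Bundle) -> dict[str, object]:
    """The worked pre-admission-medication example, step by step.

    Returns the intermediate track of each of the eight pipeline steps for
    the first stay of the bundle: stay construction, the 90-day window, the
    per-drug exposure tracks, their masking by the window, the union, and the
    final count-distinct value.
    """
    cfg = load_case_config("sc6")
    visits = _select_visits(bundle, cfg["visit_concept"])
    units = _visit_units(visits)
    umap = UnitMap.by_column(units, "visit_occurrence_id")
    stays, _ = interval_from_fields(
        visits, umap, start_field="visit_start_date", end_field="visit_end_date",
        track_concept="hospital_stay",
    )
    uid = sorted(stays)[0]
    stay = stays[uid]
    window = shift_window(
        stay, WindowSpec("start", -int(cfg["window_days"]) * DAY, _dt.timedelta(0)),
        track_concept="90_days_before",
    )
    cs = _concept_set(cfg["concept_set"]["set_id"], vocab.ATC, cfg["concept_set"]["codes"])
    expo, _ = exposure_intervals(
        bundle.tables["drug_exposure"], umap,
        concept_set=cs, code_column="drug_concept_id", vocabulary=vocab.ATC,
        track_concept="laroche_exposure",
    )
    exposures = expo.get(uid, _empty(uid, "laroche_exposure"))
    drugs = exposures.distinct_values()
    per_drug = [
        IntervalTrack(uid, "laroche_exposure",
                      [r for r in exposures.sorted_records() if r.value == d])
        for d in drugs
    ]
    masked = [
        intersect(t, window, track_concept="laroche_exposure/90_days_before")
        for t in per_drug
    ]
    joined = _empty(uid, "laroche_in_window")
    for m in masked:
        joined = union(joined, m, track_concept="laroche_in_window")
    period = window.records[0].interval
    from .aggregation import aggregate_intervals

    steps: dict[str, object] = {
        "step1_stay": stay,
        "step2_window": window,
        "step5_a_masked": masked[0] if masked else None,
        "step6_b_masked": masked[1] if len(masked) > 1 else None,
        "step7_union": joined,
        "step8_count_distinct": aggregate_intervals(joined, period, "count_distinct"),
    }
    if per_drug:
        steps["step3_drug_a"] = per_drug[0]
    if len(per_drug) > 1:
        steps["step4_drug_b"] = per_drug[1]
    return steps
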