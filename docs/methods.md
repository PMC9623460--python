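# Methods

## Time model

One study-wide, UTC-naive clock with one-second resolution; all duration
arithmetic is in integer seconds. Intervals are half-open `[start, end)`:
a point `t` belongs to the interval iff `start <= t < end`, abutting
day-level periods partition time without double counting, and
`start == end` is a zero-duration point event (an administration, a
laboratory draw). Calendar dates promote to midnight so day-level claims
data and second-level monitor data share one algebra. Time zones,
non-Gregorian calendars and sub-second resolution are out of scope.

Two conventions fill gaps the day-granular sources leave open:

* **Stays are discharge-day-inclusive**: a row with admission and discharge
  as plain dates becomes `[admission, discharge + 1 day)`, so a same-day
  stay is a real one-day stay rather than an empty interval.
* **A zero-day dispensing is a one-day exposure**: a drug row with no days
  supplied still evidences exposure on its administration day.

## Tracks

A track is the time-dependent state of one statistical unit — the element
of the population the study is conducted on (person, stay, procedure, or a
single event occurrence; every unit resolves to exactly one person).

An `IntervalTrack` is a set of valued half-open intervals. Its normal form
(`coalesce`) merges overlapping or abutting records of equal value and never
merges distinct values; coalescing is idempotent and preserves covered
duration per value. Interval algebra operates on coalesced covered time:
`intersect` carries the left operand's values (the payload∩mask idiom —
masking drug exposures by a window must keep the drug concepts for a later
count-distinct), `union` keeps distinct values as separate records for the
same reason.

A `SignalTrack` is a piecewise-constant function stored as disjoint constant
segments inside a domain; uncovered time is *undefined*, which is distinct
from any value. Irregular samples are reconstructed on a regular grid
(default one second) by last observation carried forward with a validity
horizon `max_gap` (default 600 s for vitals): monitor data are
step-archived, and after a disconnection the signal is unknown, not stale.
Linear interpolation is available as an opt-in alternative; it never
extrapolates past the last sample.

## Periods of interest and milestones

A period of interest is one half-open interval per unit, built from a start
and an end milestone plus optional signed offsets ("the 90 days preceding
admission", "10 minutes around the administration"). The same clinical
milestone may be documented under several concepts; a `MilestoneRule` lists
candidates in expert-priority order and selects the earliest (configurable:
latest) event of the highest-priority concept present, with `first`/`last`/
`error` fallback when none is. A unit whose milestones cannot be resolved,
or whose period inverts, is excluded with a logged reason — exclusions are
first-class output, and input units always equal output units plus
exclusions.

## Aggregation catalogue

Signal methods restrict the signal to the period and use only defined time:
`mean` and `weighted_average` are both the time-weighted mean (on a 1 s
resampled signal this equals the plain mean of per-second values, which is
why both names are accepted); `median` is defined as the median of the
one-second-grid values, keeping it deterministic and consistent with the
resampling convention; `min`/`max` range over defined segment values. A
period over which the signal is undefined yields *no* feature plus an
exclusion — imputing 0 would corrupt the analysis. Interval methods clip
records to the period first; counting methods (`sum_duration`, `count`,
`count_distinct`, `exists`) return the mathematically forced 0 on an empty
clip, while value-like methods (`delay`, measured in seconds from the period
start to the earliest clipped record; `first`/`last`, tie-broken by a stable
sort on (start, value)) return no feature. A single post-aggregation step,
`threshold_feature`, derives a 0/1 indicator by comparing a numeric feature
with a constant (guideline compliance).

Every feature carries the id of the `FeatureDefinition` that produced it.
The definition's seven items (source, statistical unit, track type, value
rule, final track, period, method) are serialized losslessly to YAML/JSON.

## Storage

`TRACK` rows keep the time dimension with paired date/datetime columns
(dates hold the datetime's date part; the pairing follows OMOP convention
because claims tracks are day-granular while intraoperative tracks are
second-granular). Signals are stored as one row per constant segment, not
per raw sample, to bound volume. `FEATURE` rows have no time columns;
`value_as_number`/`value_as_concept_id` split continuous from categorical
values, `episode_id` discriminates repeated occurrences per person, and
`feature_source_value` records the producing definition id.
`track_source_value` records the statistical unit, and a JSON manifest
carries the unit registry and the full definitions, so a run re-reads
losslessly. Writers sort rows and assign ids sequentially, making output
byte-deterministic; validation checks orphan person/visit references, date
order, date/datetime consistency, duplicate keys and value-slot violations.

## Synthetic data

The generator emulates the raw data of the eight case studies: irregular
vital-sign streams (inter-sample gaps uniform on 15–120 s, typical monitor
archiving), anesthesia milestones, drug exposures with day-level durations,
daily INR results, and day-granular hospital stays. Signals are generated
as ground-truth step functions *first* and then sampled so that every change
point is in the sample set: LOCF reconstruction of such samples is exact,
making the planted answer keys sharp rather than approximate, and sampling
irregularity cannot move them. Additive noise is off by default; when
enabled, the truth is defined on the noisy sampled step function, keeping
the key exact. One `numpy` generator seeded from the spec drives a run;
identical specs give byte-identical files.

What the simulation does **not** emulate: pharmacokinetics or physiology
(dips are planted rectangles, not hemodynamics), missingness mechanisms
beyond the validity-horizon gap, coding errors, or the full PMSI/SNDS/MIMIC
schemas — only the columns the operations read. Passing tests therefore
demonstrate that the transformations are correct on data whose ground truth
is known exactly, not that any clinical finding transfers to real data.

Scale used by the tests and the acceptance script: 50 units per scenario
(seed 42 in the test suite), 1000 random track pairs for the algebra
oracle, 200 random signals for the aggregation oracle — sizes chosen so the
full suite completes in seconds while exercising every code path.

## Case-specific choices

Where the case descriptions leave room, the pipelines take one documented
reading:

* The relative-drop reference for intraoperative hypotension uses a
  pre-incision baseline window (procedure start to incision) rather than
  the whole-procedure mean, which would be circular; the cesarean variant
  uses arrival-to-induction, with the induction selected by the four-concept
  priority rule.
* The pre/post windows around an atropine administration clip to the
  procedure implicitly: the signal is undefined outside it, and
  aggregations use defined time only.
* Ideal body weight is a per-person input column; no formula is applied.
* The drug-interaction observation window is applied per overlap episode —
  "the day after the two drugs were administered together" is the first day
  of each overlap, "four days after the first discontinuation" its end —
  the only reading that handles re-exposure.
* The suspected-COPD follow-up year anchors at the first COPD-specific
  exposure of any qualifying class; the administration count covers all
  three classes.
* Whole-table inclusion criteria (the ICU eligibility flag, the age cutoff)
  are applied when selecting the unit population, before track definition.

## Limitations

The concept-set matcher does exact, prefix and dot-stripped-ICD matching on
flat user-supplied lists; it does not traverse terminology hierarchies.
Storage is flat CSV, not a database; the TRACK table's datetime columns are
an extension of the day-granular design, required because four of the eight
cases are second-granular. Feature reading at event-level units relies on
the run manifest (or the `episode_id` anchor) to recover the unit; without
a registry, visit or person ids stand in.
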