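# trackfeat

Track-based feature extraction for retrospective observational studies on
OMOP-style clinical event tables.

## The problem

Raw clinical data — hospital stays, drug dispensings, laboratory results,
intraoperative monitor signals — are heterogeneous, multidimensional and
time-dependent. A retrospective study needs none of that: it needs one row
per *statistical unit* (a patient, a stay, a surgical procedure, a single
drug administration) with time-independent variables such as "seconds of
hypotension during the procedure" or "distinct inappropriate drugs in the
90 days before admission". Getting from one to the other is where most of
the analysis effort, and most of the irreproducibility, lives.

`trackfeat` structures that gap as two standardized transformations:

1. **Track definition** reduces raw records to per-unit, time-standardized
   *tracks*. A track is either a set of valued half-open intervals
   `[start, end)` (exposure episodes, stays, threshold episodes) or a
   piecewise-constant *signal* reconstructed from irregular samples by
   last-observation-carried-forward with a validity horizon. The toolkit
   covers concept-set selection with code mapping, stay/exposure interval
   construction, milestone selection by expert priority rule, artificial
   windows ("the 90 days preceding admission"), resampling to a one-second
   grid, threshold-episode detection (absolute or relative to a per-unit
   reference), and interval algebra (intersection, union, masking).
2. **Track aggregation** reduces one track over a *period of interest* to a
   single value per unit, with a closed catalogue of extraction methods:
   `min`, `max`, `mean`/`weighted_average` (the time-weighted mean),
   `median` (on the one-second grid), `sum_duration`, `count`,
   `count_distinct`, `exists`, `delay`, `first`, `last`.

Each feature is documented by a declarative `FeatureDefinition` carrying
seven items — source, statistical unit, track type, value rule, final track,
period of interest, extraction method — so the computation can be shared and
re-run without reading pipeline code. Tracks and features persist in
OMOP-compatible `TRACK` and `FEATURE` tables (CSV, with a JSON run
manifest), alongside the established derived-element tables.

The package ships a seeded synthetic-data generator (`trackfeat.simulate`)
emulating the raw data of eight reference study cases — ICU oxygenation,
intraoperative hypotension (two variants), heart rate around atropine,
ventilation compliance, pre/post-admission inappropriate medications,
VKA drug–drug interactions with INR response, and suspected-COPD screening —
each with a planted answer key, plus reference pipelines for all eight
(`trackfeat.casebook`) and a thin CLI (`trackfeat`).

## Worked example

`examples/hypotension_episodes.py` reconstructs a 30-minute irregularly
sampled systolic-pressure recording, computes a baseline reference over the
first five minutes, detects episodes more than 20 % below it, and sums their
duration:

```text
reference (baseline mean over the first 5 min): 120.58 mmHg
episode: [08:10:00, 08:14:00)
total time below 80% of reference: 240 s
```

The signal dips at 08:10:00 (samples of 90 and 88 mmHg) and the recovery is
next sampled at 08:14:00; under last-observation-carried-forward
reconstruction the hypotension episode is exactly those 240 seconds. The
other example scripts cover the worked medication-review chain step by step
(`worked_medication_review.py`), a simulated drug-interaction cohort checked
against its planted truth (`simulate_and_extract.py`), and table persistence
with validation (`store_and_validate.py`).

The same pipelines run from the shell:

```sh
trackfeat simulate --scenario sc6 --n 100 --seed 42 --out bundle/
trackfeat run-case sc6 --bundle bundle/ --out out/
trackfeat validate --tracks out/TRACK.csv --features out/FEATURE.csv \
    --person bundle/person.csv --visits bundle/visit_occurrence.csv
trackfeat describe sc6
```

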