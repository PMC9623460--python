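# Heart rate around atropine administration
case_id: sc4
title: Heart rate in the 10 minutes before and after each atropine administration
requires: [visit_occurrence, drug_exposure, measurement]
visit_concept: bradycardia_surgery
event_drug: A03BA01   # atropine; each administration is one statistical unit
signal_concept: HR
window_minutes: 10
resample: {step_s: 1, max_gap_s: 600}
definitions:
  - definition_id: sc4_hr_median_before
    feature_concept: hr_median_before
    label: Median heart rate in the 10 minutes before atropine
    source: measurement rows, concept HR; atropine administrations from drug exposures
    statistical_unit: event_occurrence
    track_type: resampled_signal
    value_rule: LOCF reconstruction to one measurement per second; windows clip to the procedure
    final_track: heart_rate
    period: before_window
    method: {name: median}
  - definition_id: sc4_hr_min_before
    feature_concept: hr_min_before
    label: Minimum heart rate in the 10 minutes before atropine
    source: measurement rows, concept HR; atropine administrations from drug exposures
    statistical_unit: event_occurrence
    track_type: resampled_signal
    value_rule: LOCF reconstruction to one measurement per second; windows clip to the procedure
    final_track: heart_rate
    period: before_window
    method: {name: min}
  - definition_id: sc4_hr_max_before
    feature_concept: hr_max_before
    label: Maximum heart rate in the 10 minutes before atropine
    source: measurement rows, concept HR; atropine administrations from drug exposures
    statistical_unit: event_occurrence
    track_type: resampled_signal
    value_rule: LOCF reconstruction to one measurement per second; windows clip to the procedure
    final_track: heart_rate
    period: before_window
    method: {name: max}
  - definition_id: sc4_hr_median_after
    feature_concept: hr_median_after
    label: Median heart rate in the 10 minutes after atropine
    source: measurement rows, concept HR; atropine administrations from drug exposures
    statistical_unit: event_occurrence
    track_type: resampled_signal
    value_rule: LOCF reconstruction to one measurement per second; windows clip to the procedure
    final_track: heart_rate
    period: after_window
    method: {name: median}
  - definition_id: sc4_hr_min_after
    feature_concept: hr_min_after
    label: Minimum heart rate in the 10 minutes after atropine
    source: measurement rows, concept HR; atropine administrations from drug exposures
    statistical_unit: event_occurrence
    track_type: resampled_signal
    value_rule: LOCF reconstruction to one measurement per second; windows clip to the procedure
    final_track: heart_rate
    period: after_window
    method: {name: min}
  - definition_id: sc4_hr_max_after
    feature_concept: hr_max_after
    label: Maximum heart rate in the 10 minutes after atropine
    source: measurement rows, concept HR; atropine administrations from drug exposures
    statistical_unit: event_occurrence
    track_type: resampled_signal
    value_rule: LOCF reconstruction to one measurement per second; windows clip to the procedure
    final_track: heart_rate
    period: after_window
    method: {name: max}
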