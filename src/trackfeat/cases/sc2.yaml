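# Duration of hypotension during heavy surgery
case_id: sc2
title: Time spent with mean arterial pressure 10 % below the reference value
requires: [visit_occurrence, procedure_occurrence, measurement]
visit_concept: heavy_surgery
anchor_concept: anesthesia_start
signal_concept: MAP
signal_track: mean_arterial_pressure
milestones:
  period_start: [anesthesia_start]
  period_end: [anesthesia_end]
  # the reference (average) value is computed over a pre-incision baseline
  # window: anesthesia start to incision
  baseline_start: [anesthesia_start]
  baseline_end: [incision]
threshold: {comparator: "<", fraction: 0.9, min_duration_s: 0, merge_gap_s: 0}
resample: {step_s: 1, max_gap_s: 600}
definitions:
  - definition_id: sc2_hypotension_duration
    feature_concept: map_hypotension_duration_s
    label: Seconds of mean arterial pressure below 90 % of the reference, during the procedure
    source: measurement rows, concept MAP; procedure milestones for the windows
    statistical_unit: procedure_occurrence
    track_type: threshold_episode
    value_rule: episodes where resampled MAP < 0.9 x mean over the pre-incision baseline window
    final_track: hypotension_episodes
    period: anesthesia_period
    method: {name: sum_duration}
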