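# Hypotension during cesarean section with spinal anesthesia
case_id: sc3
title: Time with systolic pressure 20 % below the arrival-to-induction reference
requires: [visit_occurrence, procedure_occurrence, measurement]
visit_concept: cesarean_section
anchor_concept: or_arrival
signal_concept: SAP
signal_track: systolic_arterial_pressure
milestones:
  # the start of anesthesia may be documented four ways; expert priority rule
  period_start: [induction, hypnotic, intubation, ventilation]
  period_end: [birth]
  baseline_start: [or_arrival]
  baseline_end: [induction, hypnotic, intubation, ventilation]
threshold: {comparator: "<", fraction: 0.8, min_duration_s: 0, merge_gap_s: 0}
resample: {step_s: 1, max_gap_s: 600}
definitions:
  - definition_id: sc3_hypotension_duration
    feature_concept: sap_hypotension_duration_s
    label: Seconds of systolic pressure below 80 % of the reference, induction to birth
    source: measurement rows, concept SAP; procedure milestones for the windows
    statistical_unit: procedure_occurrence
    track_type: threshold_episode
    value_rule: episodes where resampled SAP < 0.8 x mean between operating-room arrival and the selected induction event
    final_track: hypotension_episodes
    period: anesthesia_period
    method: {name: sum_duration}
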