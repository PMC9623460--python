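# Hyperoxemia in mechanically ventilated ICU patients
case_id: sc1
title: Weighted average of PaO2 over the first 24 h of ICU stay
requires: [visit_occurrence, measurement]
visit_concept: icu_stay
# inclusion (ventilated septic shock per SEPSIS-3) is supplied as a flag column
eligibility_column: eligible
signal_concept: PAO2
period_hours: 24
resample: {step_s: 1, max_gap_s: 600}
definitions:
  - definition_id: sc1_pao2_weighted_mean
    feature_concept: pao2_weighted_mean
    label: Weighted average of PaO2 during the first 24 h of ICU stay
    source: measurement rows, concept PAO2 (irregular blood-gas/monitor samples)
    statistical_unit: visit
    track_type: resampled_signal
    value_rule: LOCF reconstruction to one measurement per second, 600 s validity horizon
    final_track: pao2
    period: first_24h
    method: {name: weighted_average}
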