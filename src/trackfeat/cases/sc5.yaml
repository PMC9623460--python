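# Compliance with protective-ventilation guidelines
case_id: sc5
title: Mean end-tidal volume per kg ideal body weight during surgery
requires: [person, visit_occurrence, procedure_occurrence, measurement]
visit_concept: ventilated_surgery
anchor_concept: anesthesia_start
end_concept: anesthesia_end
signal_concept: TV
resample: {step_s: 1, max_gap_s: 600}
# ideal body weight is taken as a per-person input column (no formula applied)
definitions:
  - definition_id: sc5_tv_per_kg_mean
    feature_concept: tv_per_kg_mean
    label: Time-weighted mean of end-tidal volume / ideal body weight (mL/kg) during surgery
    source: measurement rows, concept TV; ideal body weight from the person table
    statistical_unit: procedure_occurrence
    track_type: transformed_signal
    value_rule: resampled tidal volume divided by the per-person ideal body weight
    final_track: tidal_volume_per_kg
    period: surgery_period
    method: {name: mean}
post_threshold:
  from_feature: tv_per_kg_mean
  comparator: "<"
  threshold: 8.0
  feature_concept: tv_guideline_compliant
  definition_id: sc5_tv_guideline_compliant
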