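# Potentially inappropriate medications around a hospital stay
case_id: sc6
title: Distinct flagged drugs in the 90 days before admission / after discharge
requires: [visit_occurrence, drug_exposure]
visit_concept: hospital_stay
window_days: 90
concept_set:
  set_id: laroche
  # miniature stand-in for the French Laroche PIM list
  codes: [N05BA01, N05BA04, N05BA06, N05CD03, A03AB05, N06AA09]
definitions:
  - definition_id: sc6_laroche_before
    feature_concept: laroche_count_before
    label: Number of distinct flagged drugs exposed in the 90 days before admission
    source: drug exposures (start date + days supply) filtered by the flagged-drug set
    statistical_unit: visit
    track_type: drug_exposure_period
    value_rule: exposure periods intersected with the 90-day pre-admission window
    final_track: laroche_before
    period: before_window
    method: {name: count_distinct}
  - definition_id: sc6_laroche_after
    feature_concept: laroche_count_after
    label: Number of distinct flagged drugs exposed in the 90 days after discharge
    source: drug exposures (start date + days supply) filtered by the flagged-drug set
    statistical_unit: visit
    track_type: drug_exposure_period
    value_rule: exposure periods intersected with the 90-day post-discharge window
    final_track: laroche_after
    period: after_window
    method: {name: count_distinct}
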