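# Drug-drug interactions involving vitamin K antagonists
case_id: sc7
title: INR excursions inside drug-drug-interaction observation periods
requires: [person, drug_exposure, measurement]
vka_codes: [B01AA03, B01AA04]
vka_category: VKA
partner_codes: [J01EE01, J01EC02]
partner_category: DDI_SULFONAMIDE
# the observation period starts the day after the two drugs are administered
# together and ends 4 days after the first of the two is discontinued
start_lag_days: 1
end_lag_days: 4
lab_concept: INR
inr_high: 5.0
inr_low: 1.5
study_period: ["2020-06-01", "2022-06-01"]
definitions:
  - definition_id: sc7_vka_potentiation_count
    feature_concept: vka_potentiation_count
    label: Count of observation periods with at least one INR >= 5
    source: drug exposures mapped to drug categories; INR laboratory results
    statistical_unit: person
    track_type: ddi_observation_period
    value_rule: concomitant VKA + interacting-category exposure, lagged observation window, INR >= 5 within it
    final_track: vka_potentiation
    period: study_period
    method: {name: count}
  - definition_id: sc7_vka_inhibition_count
    feature_concept: vka_inhibition_count
    label: Count of observation periods with at least one INR <= 1.5
    source: drug exposures mapped to drug categories; INR laboratory results
    statistical_unit: person
    track_type: ddi_observation_period
    value_rule: concomitant VKA + interacting-category exposure, lagged observation window, INR <= 1.5 within it
    final_track: vka_inhibition
    period: study_period
    method: {name: count}
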