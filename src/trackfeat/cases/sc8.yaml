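# Guideline compliance for suspected-COPD patients
case_id: sc8
title: Suspected COPD and respiratory exploration in the following year
requires: [person, drug_exposure, procedure_occurrence]
age_over: 40
age_reference_year: 2021
drug_classes:
  bronchodilator: {codes: [R03AC02, R03BB04], min_count: 1}
  resp_antibiotic: {codes: [J01CA04, J01FA09, J01AA02], min_count: 3}
  nicotinic: {codes: [N07BA01], min_count: 1}
fre_concept: spirometry
follow_days: 365
study_period: ["2020-06-01", "2022-06-01"]
suspect_feature: copd_suspect
definitions:
  - definition_id: sc8_copd_suspect
    feature_concept: copd_suspect
    label: Suspected COPD (age > 40 and one of the drug-class criteria met)
    source: person age; drug exposures of the three COPD-specific classes
    statistical_unit: person
    track_type: rule_met_indicator
    value_rule: bronchodilator >= 1, or respiratory antibiotics >= 3, or nicotinic substitute >= 1, with age above the cutoff
    final_track: copd_rule_met
    period: study_period
    method: {name: exists}
  - definition_id: sc8_copd_drug_count
    feature_concept: copd_drug_count_1y
    label: COPD-specific administrations in the year following the first such exposure
    source: drug exposures of the three COPD-specific classes
    statistical_unit: person
    track_type: drug_administration_event
    value_rule: administrations counted in the one-year window anchored at the first COPD-specific exposure
    final_track: copd_administrations
    period: follow_year
    method: {name: count}
  - definition_id: sc8_fre_done
    feature_concept: fre_done_1y
    label: Functional respiratory exploration performed in the year following the first exposure
    source: procedure rows, concept spirometry
    statistical_unit: person
    track_type: procedure_event
    value_rule: any spirometry / functional respiratory exploration in the one-year follow window
    final_track: fre_events
    period: follow_year
    method: {name: exists}
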