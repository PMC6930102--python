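# Default 36-item prospective frailty-index battery.
#
# Encodes the battery's domain structure: disability (items 1-14),
# cognition (15), self-rating of health and health change (16-17),
# physical status incl. the physical-frailty phenotype criteria (18-21),
# depression/exhaustion (22), and multimorbidity (23-36).
#
# ASSUMPTIONS: the instrument-level operationalisations below (which ADL/
# IADL activities, the cognitive and depression screen cut-points, the
# phenotype criteria, the physical-function tertiles) are this package's
# own one-point-per-deficit defaults, not a validated instrument. Any
# 36-item config with complete {0, 0.5, 1} mappings may replace this file.
name: prospective_36
cutoffs: [0.08, 0.25]
items:
  # -- Disability: needs help with the activity (ADL x6, IADL x8) --------
  - {id: adl_bathing, source: battery, mapping: {"Yes": 1, "No": 0}}
  - {id: adl_dressing, source: battery, mapping: {"Yes": 1, "No": 0}}
  - {id: adl_toileting, source: battery, mapping: {"Yes": 1, "No": 0}}
  - {id: adl_transferring, source: battery, mapping: {"Yes": 1, "No": 0}}
  - {id: adl_continence, source: battery, mapping: {"Yes": 1, "No": 0}}
  - {id: adl_feeding, source: battery, mapping: {"Yes": 1, "No": 0}}
  - {id: iadl_telephone, source: battery, mapping: {"Yes": 1, "No": 0}}
  - {id: iadl_shopping, source: battery, mapping: {"Yes": 1, "No": 0}}
  - {id: iadl_cooking, source: battery, mapping: {"Yes": 1, "No": 0}}
  - {id: iadl_housekeeping, source: battery, mapping: {"Yes": 1, "No": 0}}
  - {id: iadl_laundry, source: battery, mapping: {"Yes": 1, "No": 0}}
  - {id: iadl_transport, source: battery, mapping: {"Yes": 1, "No": 0}}
  - {id: iadl_medication, source: battery, mapping: {"Yes": 1, "No": 0}}
  - {id: iadl_finances, source: battery, mapping: {"Yes": 1, "No": 0}}
  # -- Cognition: screen positive for cognitive impairment ---------------
  - {id: cognitive_impairment, source: battery, mapping: {"Yes": 1, "No": 0},
     note: "cognitive screen below the impairment cut-point"}
  # -- Self-rating of health and change in health ------------------------
  - {id: self_rated_health, source: battery,
     mapping: {"Poor": 1, "Fair": 0.5, "Good": 0, "Very good": 0, "Excellent": 0}}
  - {id: self_rated_health_change, source: battery,
     mapping: {"Much worse": 1, "Somewhat worse": 0.5, "Same": 0,
               "Somewhat better": 0, "Much better": 0}}
  # -- Physical status ----------------------------------------------------
  - {id: physical_function_low, source: battery,
     mapping: {"Low": 1, "Intermediate": 0.5, "High": 0},
     note: "physical-functioning score tertile"}
  - {id: phenotype_weight_loss, source: battery, mapping: {"Yes": 1, "No": 0}}
  - {id: phenotype_weakness, source: battery, mapping: {"Yes": 1, "No": 0}}
  - {id: phenotype_slowness, source: battery, mapping: {"Yes": 1, "No": 0}}
  # -- Depression / exhaustion --------------------------------------------
  - {id: depression_exhaustion, source: battery, mapping: {"Yes": 1, "No": 0},
     note: "depression screen above the cut-point"}
  # -- Multimorbidity: 14 medical-history conditions ----------------------
  - {id: cmb_high_blood_pressure, source: comorbidity, column: high_blood_pressure,
     mapping: {present: 1, absent: 0}}
  - {id: cmb_diabetes, source: comorbidity, column: diabetes,
     mapping: {present: 1, absent: 0}}
  - {id: cmb_cancer, source: comorbidity, column: cancer,
     mapping: {present: 1, absent: 0}}
  - {id: cmb_chronic_lung_disease, source: comorbidity, column: chronic_lung_disease,
     mapping: {present: 1, absent: 0}}
  - {id: cmb_myocardial_infarction, source: comorbidity, column: myocardial_infarction,
     mapping: {present: 1, absent: 0}}
  - {id: cmb_congestive_heart_failure, source: comorbidity, column: congestive_heart_failure,
     mapping: {present: 1, absent: 0}}
  - {id: cmb_angina, source: comorbidity, column: angina,
     mapping: {present: 1, absent: 0}}
  - {id: cmb_asthma, source: comorbidity, column: asthma,
     mapping: {present: 1, absent: 0}}
  - {id: cmb_arthritis, source: comorbidity, column: arthritis,
     mapping: {present: 1, absent: 0}}
  - {id: cmb_stroke, source: comorbidity, column: stroke,
     mapping: {present: 1, absent: 0}}
  - {id: cmb_kidney_disease, source: comorbidity, column: kidney_disease,
     mapping: {present: 1, absent: 0}}
  - {id: cmb_liver_disease, source: comorbidity, column: liver_disease,
     mapping: {present: 1, absent: 0}}
  - {id: cmb_thyroid_disease, source: comorbidity, column: thyroid_disease,
     mapping: {present: 1, absent: 0}}
  - {id: cmb_osteoporosis, source: comorbidity, column: osteoporosis,
     mapping: {present: 1, absent: 0}}
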