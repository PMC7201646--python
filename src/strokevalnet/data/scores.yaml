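# Point / coefficient tables for the five stroke-risk models, restricted to the
# covariates available under the study missing-data policy. The validated
# source papers print covariate membership but not weights, so every weight
# below is transcribed from the model's own development publication and frozen
# under test. Age bands are closed integer-year intervals and exhaustively
# cover all ages (zero-weight default bands included).
#
# excluded_predictors lists development-model terms dropped (not renormalised)
# because they are rarely recorded in claims data or are UK-specific.

CHADS2:
  # Gage et al. 2001, JAMA 285(22): 1 point each for congestive heart failure,
  # hypertension, age >= 75, diabetes; 2 points for prior stroke/TIA.
  output_kind: integer_points
  valid_range: [0, 6]
  age_bands:
    - {min: 0, max: 74, weight: 0}
    - {min: 75, max: 150, weight: 1}
  points:
    congestive_heart_failure: 1
    hypertension: 1
    diabetes: 1
    prior_stroke_tia: 2
  excluded_predictors: []

CHA2DS2VASc:
  # Lip et al. 2010, Chest 137(2): CHF 1, hypertension 1, age >= 75 -> 2,
  # diabetes 1, stroke/TIA 2, vascular disease 1, age 65-74 -> 1, female sex 1.
  output_kind: integer_points
  valid_range: [0, 9]
  age_bands:
    - {min: 0, max: 64, weight: 0}
    - {min: 65, max: 74, weight: 1}
    - {min: 75, max: 150, weight: 2}
  points:
    congestive_heart_failure: 1
    hypertension: 1
    diabetes: 1
    prior_stroke_tia: 2
    vascular_disease: 1
    female: 1
  excluded_predictors: []

ATRIA:
  # Singer et al. 2013, J Am Heart Assoc 2(3) — no-prior-stroke column of the
  # ATRIA point table: age 85+ -> 6, 75-84 -> 5, 65-74 -> 3, <65 -> 0;
  # female 1, diabetes 1, CHF 1, hypertension 1, proteinuria 1,
  # eGFR < 45 or ESRD 1.
  output_kind: integer_points
  valid_range: [0, 12]
  age_bands:
    - {min: 0, max: 64, weight: 0}
    - {min: 65, max: 74, weight: 3}
    - {min: 75, max: 84, weight: 5}
    - {min: 85, max: 150, weight: 6}
  points:
    female: 1
    diabetes: 1
    congestive_heart_failure: 1
    hypertension: 1
    proteinuria: 1
    esrd_or_low_egfr: 1
  excluded_predictors: []

Framingham:
  # Wang et al. 2003, JAMA 290(8) — stroke-in-AF point score, no-prior-stroke
  # model: age <60 -> 0 rising to >93 -> 10; female 6; diabetes 5. The systolic
  # blood-pressure points (0-4) are dropped, not renormalised, because the
  # measurement is rarely recorded in claims data.
  output_kind: integer_points
  valid_range: [0, 21]
  age_bands:
    - {min: 0, max: 59, weight: 0}
    - {min: 60, max: 62, weight: 1}
    - {min: 63, max: 66, weight: 2}
    - {min: 67, max: 71, weight: 3}
    - {min: 72, max: 74, weight: 4}
    - {min: 75, max: 77, weight: 5}
    - {min: 78, max: 81, weight: 6}
    - {min: 82, max: 85, weight: 7}
    - {min: 86, max: 90, weight: 8}
    - {min: 91, max: 93, weight: 9}
    - {min: 94, max: 150, weight: 10}
  points:
    female: 6
    diabetes: 5
  excluded_predictors: [systolic_bp]

QStroke:
  # Hippisley-Cox et al. 2013, BMJ 346 — female model, reduced to the terms
  # recordable in claims data. Weights are log hazard ratios rounded from the
  # published female-model hazard ratios; the continuous age effect
  # (~0.06/year) is discretised into decade bands. Townsend score, ethnicity,
  # smoking-intensity detail, blood pressure and cholesterol ratio terms are
  # dropped; smoking collapses to a single ever-smoker flag. Only the ranking
  # of the linear predictor feeds evaluation, so the reduced predictor is used
  # directly (no 10-year risk transformation).
  output_kind: linear_predictor
  valid_range: [0.0, 7.75]
  age_bands:
    - {min: 0, max: 44, weight: 0.0}
    - {min: 45, max: 54, weight: 0.55}
    - {min: 55, max: 64, weight: 1.15}
    - {min: 65, max: 74, weight: 1.75}
    - {min: 75, max: 84, weight: 2.35}
    - {min: 85, max: 150, weight: 2.95}
  points:
    atrial_fibrillation: 0.96
    hypertension: 0.34
    diabetes: 0.43
    chf_or_liver_disease: 0.45
    smoker: 0.51
    coronary_heart_disease: 0.49
    family_history_chf: 0.30
    rheumatoid_arthritis: 0.27
    chronic_renal_disease: 0.56
    valvular_heart_disease: 0.49
  excluded_predictors: [townsend_score, ethnicity, systolic_bp, cholesterol_ratio]
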