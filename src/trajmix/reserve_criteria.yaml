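# Physiologic reserve index deficit criteria, version 1.
# Each entry dichotomizes one health variable: the measurement is scored a
# DEFICIT when its predicate holds, otherwise NORMAL.  Inequalities are
# strict unless stated (ge = deficit when measurement >= threshold), so
# boundary values are normal except for triglycerides.  Sex-specific items
# dispatch on recorded sex.  Note the hemoglobin cutoffs are expressed in
# the source units as printed (umol/l), where g/dl is conventional.
version: 1
items:
  - {name: bmi, label: "Abnormal BMI", units: "kg/m^2", kind: outside, lo: 18, hi: 25}
  - {name: wbc, label: "Low white blood cell count", units: "cells/ul", kind: low, value: 4000}
  - {name: mchc, label: "Abnormal MCHC", units: "g/dl", kind: outside_sex,
     male: {lo: 27.8, hi: 33.8}, female: {lo: 26.9, hi: 33.3}}
  - {name: bun, label: "Abnormal BUN", units: "mg/dl", kind: outside, lo: 8, hi: 23}
  - {name: creatinine, label: "Abnormal creatinine", units: "mg/dl", kind: outside, lo: 0.6, hi: 1.2}
  - {name: calcium, label: "Abnormal calcium", units: "mg/dl", kind: outside, lo: 9.2, hi: 10.8}
  - {name: chloride, label: "Abnormal chloride", units: "mEq/l", kind: outside, lo: 96, hi: 106}
  - {name: total_protein, label: "Abnormal total protein (serum)", units: "mg", kind: outside, lo: 6, hi: 7.8}
  - {name: albumin, label: "Low albumin (serum)", units: "mg", kind: low, value: 3.5}
  - {name: fibrinogen, label: "Elevated fibrinogen", units: "", kind: high, value: 3.25}
  - {name: egfr, label: "Low eGFR", units: "ml/min/1.73m^2", kind: low, value: 60}
  - {name: hemoglobin, label: "Low hemoglobin", units: "umol/l", kind: low_sex,
     male: 12, female: 10}
  - {name: ast, label: "Elevated AST", units: "U/l", kind: high, value: 31}
  - {name: alt, label: "Elevated ALT", units: "U/l", kind: high, value: 31}
  - {name: alp, label: "Abnormal ALP", units: "U/l", kind: outside, lo: 38, hi: 126}
  - {name: potassium, label: "Abnormal potassium", units: "mEq/l", kind: outside, lo: 3.5, hi: 5.3}
  - {name: bilirubin, label: "Elevated total bilirubin", units: "mg/dl", kind: high, value: 1.1}
  - {name: triglycerides, label: "Elevated triglycerides", units: "mg/dl", kind: ge, value: 150}
  - {name: cholesterol, label: "Elevated total cholesterol", units: "mg/dl", kind: high, value: 200}
  - {name: hdl, label: "Low HDL cholesterol", units: "mg/dl", kind: low_sex,
     male: 40, female: 50}
  - {name: glucose, label: "Elevated glucose", units: "mg/dl", kind: high, value: 200}
  - {name: weight_loss, label: "Weight loss > 10 lbs in past year", units: "bool", kind: flag}
  - {name: platelets, label: "Low platelets", units: "billion/l", kind: low, value: 150}
  - {name: hcv, label: "HCV", units: "bool", kind: flag}
  - {name: diabetes, label: "Diabetes mellitus", units: "bool", kind: flag}
  - {name: copd, label: "COPD", units: "bool", kind: flag}
  - {name: malignancy, label: "Malignancy", units: "bool", kind: flag}
  - {name: myocardial_infarction, label: "Myocardial infarction", units: "bool", kind: flag}
  - {name: renal_disease, label: "Renal disease", units: "bool", kind: flag}
  - {name: hypertension, label: "Hypertension", units: "dx flag + mmHg", kind: hypertension,
     systolic: 130, diastolic: 85}
  - {name: hyperlipidemia, label: "Hyperlipidemia", units: "bool", kind: flag}
  - {name: cerebrovascular_accident, label: "Cerebrovascular accident", units: "bool", kind: flag}
  - {name: sensory_neuropathy, label: "Sensory neuropathy", units: "bool", kind: flag}
  - {name: neuropathic_pain, label: "Distal neuropathic pain", units: "bool", kind: flag}
  - {name: smoking, label: "Smoking (ever)", units: "bool", kind: flag}
  - {name: current_cd4, label: "Low current CD4", units: "cells/ul", kind: low, value: 500}
  - {name: nadir_cd4, label: "Nadir CD4", units: "cells/ul", kind: low, value: 200}
  - {name: hiv_rna, label: "Detectable plasma HIV RNA", units: "copies/ml", kind: high, value: 40}
  - {name: disease_duration, label: "Duration of disease", units: "years", kind: high, value: 10}
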