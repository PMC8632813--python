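# Two-center baseline-characteristics spec: per-outcome-stratum summaries
# (mean/sd for continuous, category counts for categorical) for a TAVI cohort.
# Category counts that do not sum to the stratum size leave the residual as
# missing values. Note: the source table's aortic_valve_area sd for center A
# non-survivors is recorded here as 0.2 (the printed "2" is a misprint; all
# other strata of the same variable read 0.2 and a 2 cm2 spread is not
# physiologic).
schema:
  - {name: sex, kind: categorical, units: "", categories: [Male, Female]}
  - {name: age, kind: continuous, units: "year"}
  - {name: copd, kind: categorical, units: "", categories: ["No", "Yes"]}
  - {name: diabetes, kind: categorical, units: "", categories: ["No", "Yes"]}
  - {name: bmi, kind: continuous, units: "kg/m2"}
  - {name: creatinine, kind: continuous, units: "umol/L"}
  - {name: smoking, kind: categorical, units: "", categories: ["No", "Former", "Yes"]}
  - {name: beta_blockers, kind: categorical, units: "", categories: ["No", "Yes"]}
  - {name: hemoglobin, kind: continuous, units: "mmol/L"}
  - {name: qrs_duration, kind: continuous, units: "msec"}
  - {name: aortic_valve_area, kind: continuous, units: "cm2"}
  - {name: aortic_valve_peak_gradient, kind: continuous, units: "mmHg"}
  - {name: aortic_valve_mean_gradient, kind: continuous, units: "mmHg"}
  - {name: previous_mi, kind: categorical, units: "", categories: ["No", "Yes"]}
  - {name: nyha_class, kind: categorical, units: "", categories: ["1", "2", "3", "4"]}
  - {name: previous_devices, kind: categorical, units: "", categories: ["No", "Yes"]}

centers:
  A:
    n_survived: 1039
    n_died: 121
    survived:
      sex: {Male: 587, Female: 452}
      age: {mean: 81, sd: 7}
      copd: {"No": 755, "Yes": 282}
      diabetes: {"No": 720, "Yes": 313}
      bmi: {mean: 28, sd: 5}
      creatinine: {mean: 98, sd: 41}
      smoking: {"No": 479, "Former": 456, "Yes": 104}
      beta_blockers: {"No": 596, "Yes": 437}
      hemoglobin: {mean: 7.8, sd: 1}
      qrs_duration: {mean: 104, sd: 26}
      aortic_valve_area: {mean: 0.8, sd: 0.2}
      aortic_valve_peak_gradient: {mean: 68, sd: 23}
      aortic_valve_mean_gradient: {mean: 43, sd: 16}
      previous_mi: {"No": 851, "Yes": 187}
      nyha_class: {"1": 28, "2": 220, "3": 473, "4": 76}
      previous_devices: {"No": 937, "Yes": 102}
    died:
      sex: {Male: 61, Female: 60}
      age: {mean: 83, sd: 7}
      copd: {"No": 66, "Yes": 55}
      diabetes: {"No": 79, "Yes": 42}
      bmi: {mean: 27, sd: 6}
      creatinine: {mean: 120, sd: 56}
      smoking: {"No": 59, "Former": 49, "Yes": 13}
      beta_blockers: {"No": 80, "Yes": 40}
      hemoglobin: {mean: 7.7, sd: 1}
      qrs_duration: {mean: 107, sd: 27}
      aortic_valve_area: {mean: 0.8, sd: 0.2}
      aortic_valve_peak_gradient: {mean: 64, sd: 26}
      aortic_valve_mean_gradient: {mean: 44, sd: 19}
      previous_mi: {"No": 91, "Yes": 30}
      nyha_class: {"1": 1, "2": 17, "3": 82, "4": 21}
      previous_devices: {"No": 104, "Yes": 17}
  B:
    n_survived: 564
    n_died: 67
    survived:
      sex: {Male: 303, Female: 261}
      age: {mean: 81, sd: 6}
      copd: {"No": 464, "Yes": 98}
      diabetes: {"No": 241, "Yes": 142}
      bmi: {mean: 27, sd: 4}
      creatinine: {mean: 108, sd: 62}
      smoking: {"No": 392, "Former": 41, "Yes": 131}
      beta_blockers: {"No": 498, "Yes": 66}
      hemoglobin: {mean: 7.9, sd: 1.0}
      qrs_duration: {mean: 110, sd: 29}
      aortic_valve_area: {mean: 0.7, sd: 0.2}
      aortic_valve_peak_gradient: {mean: 77, sd: 24}
      aortic_valve_mean_gradient: {mean: 46, sd: 16}
      previous_mi: {"No": 387, "Yes": 105}
      nyha_class: {"1": 9, "2": 59, "3": 184, "4": 49}
      previous_devices: {"No": 417, "Yes": 52}
    died:
      sex: {Male: 46, Female: 21}
      age: {mean: 80, sd: 6}
      copd: {"No": 48, "Yes": 19}
      diabetes: {"No": 47, "Yes": 20}
      bmi: {mean: 26, sd: 4}
      creatinine: {mean: 116, sd: 46}
      smoking: {"No": 51, "Former": 4, "Yes": 12}
      beta_blockers: {"No": 53, "Yes": 14}
      hemoglobin: {mean: 7.5, sd: 0.9}
      qrs_duration: {mean: 121, sd: 33}
      aortic_valve_area: {mean: 0.7, sd: 0.2}
      aortic_valve_peak_gradient: {mean: 71, sd: 32}
      aortic_valve_mean_gradient: {mean: 39, sd: 20}
      previous_mi: {"No": 36, "Yes": 16}
      nyha_class: {"1": 4, "2": 5, "3": 24, "4": 9}
      previous_devices: {"No": 36, "Yes": 12}
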