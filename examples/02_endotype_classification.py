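"""Screen subjects for diabetes and assign endotype clusters and strata.

Three synthetic subjects illustrate the decision rules: diabetes if HbA1c
exceeds 6.5% or fasting glucose reaches 7.0 mmol/L (antidiabetic
medication also counts); diabetics are sub-classified by antibody status,
age at diagnosis, BMI and HOMA-IR; haptoglobin is dichotomised at
209.8 mg/dL and CRP at 5 mg/dL.
"""

from glycendo import FastingSample, SubjectRecord, classify, compute_panel

subjects = [
    SubjectRecord(subject_id="obese-dm", group="HS", sex="female", age=48.0,
                  bmi=34.0, sample=FastingSample(7.4, 210.0, hba1c=7.0),
                  haptoglobin=256.6, crp=11.4,
                  age_at_diabetes_diagnosis=45.0,
                  antidiabetic_medications=frozenset({"metformin"})),
    SubjectRecord(subject_id="lean-dm", group="HS", sex="male", age=52.0,
                  bmi=24.0, sample=FastingSample(7.2, 40.0, hba1c=6.9),
                  haptoglobin=197.4, crp=4.0,
                  age_at_diabetes_diagnosis=50.0),
    SubjectRecord(subject_id="healthy", group="control", sex="male", age=40.0,
                  bmi=27.4, sample=FastingSample(4.9, 69.0),
                  haptoglobin=150.0, crp=2.0),
]

print(f"{'subject':<10}{'diabetes':<10}{'cluster':<9}{'hp':<9}{'crp':<9}treated")
for s in subjects:
    lab = classify(s, compute_panel(s.sample))
    print(f"{s.subject_id:<10}{str(lab.diabetes):<10}{lab.cluster.value:<9}"
          f"{lab.haptoglobin_stratum.value:<9}{lab.crp_stratum.value:<9}{lab.treated}")

print()
print("The obese diabetic lands in MOD (obesity-related diabetes), the lean one")
print("in SIDD (insulin-deficient); the control is non-diabetic, cluster 'none'.")
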