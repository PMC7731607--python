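"""Score a single admission record and print the component breakdown."""

from vbacscore import AdmissionRecord, vbac_score, johnson_efw

# a 22-year-old at 39 completed weeks, primary cesarean for IUGR, Bishop 5,
# BMI 27, fetal weight estimated clinically from fundal height (unengaged head)
record = AdmissionRecord(
    age=22,
    gestational_age=39.0,
    indication="IUGR",          # free-text aliases are mapped to categories
    bishop=5,
    bmi=27.0,
    sfh_cm=33.0,
    engaged=False,
)

print(f"Johnson EFW: {johnson_efw(33.0, engaged=False):.0f} g")
b = vbac_score(record)
print(f"components: age={b.age_pts} ga={b.ga_pts} indication={b.indication_pts} "
      f"bishop={b.bishop_pts} bmi={b.bmi_pts} efw={b.efw_pts}")
print(f"total score: {b.total} / 12  (bin {b.bin.label})")
# The total places the patient in a reporting bin; in the development cohort
# bins 0-3 / 4-6 / 7-9 / >=10 had observed success rates 34 / 68 / 90 / 97%.
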