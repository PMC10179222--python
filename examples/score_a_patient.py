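"""Score a single hand-entered ultrasound examination.

Builds a record for a child with basal interstitial change (B-lines and an
abnormal pleural line in the lower fields), one 30-mm consolidation and a
couple of Am-lines, then prints the per-area grade breakdown and the total.
"""

from cflus import (
    FieldFindings,
    LungField,
    PatientRecord,
    PleuralFluid,
    PleuralSeverity,
    empty_findings,
    score_patient,
    validate_record,
)

findings = empty_findings()
# right anterior lower field: numerous B-lines over a ragged pleural line
findings[LungField.aLR] = FieldFindings(
    b_line_count=5, pleural_line=PleuralSeverity.present, small_consolidation_count=2
)
# right posterior lower field: a 30 mm consolidation with surrounding B-lines
findings[LungField.pLR] = FieldFindings(
    b_line_count=3, major_consolidation_sizes_mm=[30.0],
    pleural_line=PleuralSeverity.marked,
)
# left posterior base: a couple of Am-lines (bronchiectasis-like change)
findings[LungField.pLL] = FieldFindings(b_line_count=2, am_line_count=2)

record = PatientRecord(
    patient_id="demo-001",
    age_years=11.5,
    group="cf",
    findings=findings,
    pleural_fluid=[
        PleuralFluid(side="left", layer_thickness_mm=0.0),
        PleuralFluid(side="right", layer_thickness_mm=3.0),
    ],
)
assert validate_record(record) == []

result = score_patient(record)
print(f"patient {record.patient_id}, age {record.age_years} y")
print("area   small major pleural am b-lines bonus subtotal")
for a in result.per_area:
    print(
        f"{a.area.value:5s}  {a.small_consolidations:5d} {a.major_consolidations:5d}"
        f" {a.pleural_line:7d} {a.am_lines:2d} {a.b_lines:7d} {a.b_line_bonus:5d}"
        f" {a.subtotal:8d}"
    )
print(f"total: {result.total} / 44")
print(
    "Each area grades five finding categories 0-2; the bonus point marks\n"
    "B-lines present in all three fields of an area.  Higher totals mean\n"
    "more severe structural lung disease; pleural fluid (3 mm right base\n"
    "here) is reported but never scored."
)
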