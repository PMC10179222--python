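"""Domain model for per-field lung-ultrasound findings in cystic fibrosis.

The chest is divided into 12 lung fields (anterior/posterior x upper/middle/
lower x left/right), grouped into 4 scoring areas of 3 fields each (one lung
side x one surface).  A patient record carries the sonographic findings for
every field, a per-hemithorax pleural-fluid measurement, and the clinical
covariates used by the cohort analyses (age, radiograph item grades,
pulmonary-function results, microbiological status).
"""

from __future__ import annotations

import enum
from typing import Dict, List, Optional

from pydantic import BaseModel, ConfigDict, Field


class LungField(str, enum.Enum):
    """One of the 12 lung fields: (a)nterior/(p)osterior, Upper/Middle/Lower, Left/Right."""

    aUL = "aUL"
    aUR = "aUR"
    aML = "aML"
    aMR = "aMR"
    aLL = "aLL"
    aLR = "aLR"
    pUL = "pUL"
    pUR = "pUR"
    pML = "pML"
    pMR = "pMR"
    pLL = "pLL"
    pLR = "pLR"


class LungArea(str, enum.Enum):
    """One of the 4 scoring areas: lung side (Right/Left) x surface (Anterior/Posterior)."""

    RL_A = "RL-A"
    RL_P = "RL-P"
    LL_A = "LL-A"
    LL_P = "LL-P"


#: The 3 lung fields belonging to each scoring area.
AREA_FIELDS: Dict[LungArea, tuple] = {
    LungArea.RL_A: (LungField.aUR, LungField.aMR, LungField.aLR),
    LungArea.RL_P: (LungField.pUR, LungField.pMR, LungField.pLR),
    LungArea.LL_A: (LungField.aUL, LungField.aML, LungField.aLL),
    LungArea.LL_P: (LungField.pUL, LungField.pML, LungField.pLL),
}

_FIELD_TO_AREA: Dict[LungField, LungArea] = {
    f: a for a, fields in AREA_FIELDS.items() for f in fields
}


def area_of_field(field: "LungField | str") -> LungArea:
    """Map a lung-field code to its scoring area.

    Right-side fields map to ``RL-*``, anterior fields to ``*-A``.

    Raises
    ------
    ValueError
        If ``field`` is not one of the 12 field codes.
    """
    try:
        field = LungField(field)
    except ValueError:
        raise ValueError(f"unknown lung-field code: {field!r}") from None
    return _FIELD_TO_AREA[field]


class PleuralSeverity(str, enum.Enum):
    """Ordinal severity of pleural-line abnormality in one field.

    The underlying morphologies (irregularity, fragmentation, blurring,
    ragging, thickening) are collapsed by the sonographer into a single
    ordinal judgment; they may be kept as free-text tags.
    """

    absent = "absent"
    minimal = "minimal"
    present = "present"
    marked = "marked"

    @property
    def rank(self) -> int:
        return _SEVERITY_RANK[self]


_SEVERITY_RANK = {
    PleuralSeverity.absent: 0,
    PleuralSeverity.minimal: 1,
    PleuralSeverity.present: 2,
    PleuralSeverity.marked: 3,
}


class PathogenStatus(str, enum.Enum):
    """Microbiological status with respect to classical/emerging CF pathogens."""

    none = "none"
    first_time = "first_time"
    previously_reported = "previously_reported"
    intermittent = "intermittent"
    chronic = "chronic"


class FieldFindings(BaseModel):
    """Sonographic findings for a single lung field.

    ``b_line_count`` is the maximum number of B-lines seen in a single scan
    of this field; ``confluent_b`` is flagged separately because confluence
    grades as abnormal irrespective of the count.  Small consolidations
    (<=10 mm) are counted, not sized; each major consolidation (>10 mm) is
    recorded by its largest dimension in mm.
    """

    model_config = ConfigDict(validate_assignment=True)

    b_line_count: int = Field(0, ge=0)
    confluent_b: bool = False
    i_lines: bool = False
    z_lines: bool = False
    am_line_count: int = Field(0, ge=0)
    small_consolidation_count: int = Field(0, ge=0)
    major_consolidation_sizes_mm: List[float] = Field(default_factory=list)
    pleural_line: PleuralSeverity = PleuralSeverity.absent
    pleural_line_tags: List[str] = Field(default_factory=list)


class PleuralFluid(BaseModel):
    """Pleural-fluid layer thickness (mm) for one hemithorax; fluid collects basally."""

    side: str = Field(pattern="^(left|right)$")
    layer_thickness_mm: float = Field(0.0, ge=0.0)


class RadiographItems(BaseModel):
    """Item grades of a modified Chrispin-Norman chest-radiograph score.

    ``chest_configuration`` holds the named configuration items (e.g.
    sternal bowing); ``zone_shadows`` holds per-zone shadow-type grades keyed
    ``"<zone>:<shadow_type>"``.  All grades are 0/1/2.
    """

    chest_configuration: Dict[str, int] = Field(default_factory=dict)
    zone_shadows: Dict[str, int] = Field(default_factory=dict)


class PatientRecord(BaseModel):
    """One patient's ultrasound findings plus clinical covariates."""

    model_config = ConfigDict(validate_assignment=True)

    patient_id: str
    age_years: float = Field(gt=0.0)
    group: str = Field("cf", pattern="^(cf|control)$")
    findings: Dict[LungField, FieldFindings]
    pleural_fluid: List[PleuralFluid] = Field(default_factory=list)
    radiograph: Optional[RadiographItems] = None
    fev1_pct_pred: Optional[float] = Field(None, gt=0.0)
    fvc_pct_pred: Optional[float] = Field(None, gt=0.0)
    lci: Optional[float] = Field(None, gt=0.0)
    cf_pathogen_status: PathogenStatus = PathogenStatus.none
    fungal_infection: bool = False

    def field_findings(self, field: "LungField | str") -> FieldFindings:
        return self.findings[LungField(field)]

    def has_pathogen(self) -> bool:
        return self.cf_pathogen_status is not PathogenStatus.none


def empty_findings() -> Dict[LungField, FieldFindings]:
    """An all-absent findings map covering the 12 fields (a vacuous record)."""
    return {f: FieldFindings() for f in LungField}


def default_pleural_fluid() -> List[PleuralFluid]:
    return [
        PleuralFluid(side="left", layer_thickness_mm=0.0),
        PleuralFluid(side="right", layer_thickness_mm=0.0),
    ]


def validate_record(record: PatientRecord, strict: bool = True) -> List[str]:
    """Check a record against the domain invariants.

    Returns a list of violation messages, each naming the offending field
    path; an empty list means the record is valid.  With ``strict=False``
    the age-range check (ages are expected in (0, 19], covering infancy to
    18 years with slack) is reported as a warning prefix rather than a
    violation.

    Validation is idempotent: re-validating a record that came back clean
    reports nothing new.
    """
    violations: List[str] = []

    present = set(record.findings)
    for f in LungField:
        if f not in present:
            violations.append(f"findings: missing lung field {f.value}")

    for f, ff in sorted(record.findings.items(), key=lambda kv: kv[0].value):
        path = f"findings[{f.value}]"
        for attr in ("b_line_count", "am_line_count", "small_consolidation_count"):
            if getattr(ff, attr) < 0:
                violations.append(f"{path}.{attr}: negative count")
        for size in ff.major_consolidation_sizes_mm:
            if size <= 10:
                violations.append(
                    f"{path}.major_consolidation_sizes_mm: size {size} must exceed 10 mm"
                )

    sides = sorted(pf.side for pf in record.pleural_fluid)
    if sides != ["left", "right"]:
        violations.append(
            f"pleural_fluid: expected one entry per hemithorax, got sides {sides}"
        )
    for pf in record.pleural_fluid:
        if pf.layer_thickness_mm < 0:
            violations.append(f"pleural_fluid[{pf.side}]: negative layer thickness")

    if not (0 < record.age_years <= 19):
        msg = f"age_years: {record.age_years} outside (0, 19]"
        if strict:
            violations.append(msg)

    if record.radiograph is not None:
        for name, grade in record.radiograph.chest_configuration.items():
            if grade not in (0, 1, 2):
                violations.append(f"radiograph.chest_configuration[{name}]: grade {grade} not in {{0,1,2}}")
        for key, grade in record.radiograph.zone_shadows.items():
            if grade not in (0, 1, 2):
                violations.append(f"radiograph.zone_shadows[{key}]: grade {grade} not in {{0,1,2}}")

    return violations
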