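"""Shared fixtures: random finding records and an independent rule-table
oracle for the ultrasound score."""

from __future__ import annotations

from typing import Dict

import numpy as np
import pytest

from cflus.findings import (
    AREA_FIELDS,
    FieldFindings,
    LungField,
    PatientRecord,
    PleuralFluid,
    PleuralSeverity,
    empty_findings,
)

SEVERITIES = list(PleuralSeverity)


def random_findings(rng: np.random.Generator) -> FieldFindings:
    """A random single-field finding covering every grading boundary."""
    n_major = rng.choice([0, 0, 0, 1, 1, 2])
    return FieldFindings(
        b_line_count=int(rng.choice([0, 0, 1, 2, 3, 4, 5, 8])),
        confluent_b=bool(rng.random() < 0.15),
        i_lines=bool(rng.random() < 0.5),
        z_lines=bool(rng.random() < 0.5),
        am_line_count=int(rng.choice([0, 0, 0, 1, 2, 3, 5])),
        small_consolidation_count=int(rng.choice([0, 0, 1, 2, 3, 4, 6])),
        major_consolidation_sizes_mm=[
            float(v) for v in rng.uniform(10.5, 60.0, size=n_major).round(1)
        ],
        pleural_line=SEVERITIES[rng.integers(4)],
    )


def random_record(rng: np.random.Generator, pid: str = "p1") -> PatientRecord:
    return PatientRecord(
        patient_id=pid,
        age_years=float(rng.uniform(0.2, 18.0)),
        group="cf",
        findings={f: random_findings(rng) for f in LungField},
        pleural_fluid=[
            PleuralFluid(side="left", layer_thickness_mm=float(rng.choice([0, 0, 3.0]))),
            PleuralFluid(side="right", layer_thickness_mm=float(rng.choice([0, 0, 5.0]))),
        ],
    )


def oracle_total(record: PatientRecord) -> int:
    """Independent naive evaluator that walks the score's rule table cell by
    cell per area.  Deliberately written without the scoring module."""
    total = 0
    for area, fields in AREA_FIELDS.items():
        ff = [record.findings[f] for f in fields]

        small = sum(x.small_consolidation_count for x in ff)
        if small <= 1:
            total += 0
        elif 2 <= small <= 3:
            total += 1
        else:
            total += 2

        sizes = [s for x in ff for s in x.major_consolidation_sizes_mm]
        if len(sizes) == 0:
            total += 0
        elif len(sizes) == 1 and sizes[0] <= 40:
            total += 1
        else:
            total += 2

        ranks = [x.pleural_line for x in ff]
        n_present = sum(r is PleuralSeverity.present for r in ranks)
        if any(r is PleuralSeverity.marked for r in ranks) or n_present >= 2:
            total += 2
        elif n_present == 1:
            total += 1

        am = sum(x.am_line_count for x in ff)
        if am == 0:
            total += 0
        elif am <= 2:
            total += 1
        else:
            total += 2

        numerous = [x.b_line_count >= 4 for x in ff]
        if sum(numerous) >= 2:
            total += 2
        elif sum(numerous) == 1 or any(x.confluent_b for x in ff):
            total += 1
        if all(x.b_line_count >= 1 for x in ff):
            total += 1
    return total


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230424)


@pytest.fixture
def vacuous_record() -> PatientRecord:
    """All-absent record: every grade and the total must be zero."""
    return PatientRecord(
        patient_id="zero",
        age_years=7.0,
        group="cf",
        findings=empty_findings(),
        pleural_fluid=[
            PleuralFluid(side="left", layer_thickness_mm=0.0),
            PleuralFluid(side="right", layer_thickness_mm=0.0),
        ],
    )


@pytest.fixture
def saturated_record() -> PatientRecord:
    """Record saturating every category in every area (total 44)."""
    findings: Dict[LungField, FieldFindings] = {}
    for f in LungField:
        findings[f] = FieldFindings(
            b_line_count=4,
            confluent_b=True,
            am_line_count=3,
            small_consolidation_count=4,
            major_consolidation_sizes_mm=[45.0, 30.0],
            pleural_line=PleuralSeverity.marked,
        )
    return PatientRecord(
        patient_id="max",
        age_years=17.0,
        group="cf",
        findings=findings,
        pleural_fluid=[
            PleuralFluid(side="left", layer_thickness_mm=5.0),
            PleuralFluid(side="right", layer_thickness_mm=5.0),
        ],
    )
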