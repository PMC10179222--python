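"""CSV/JSON round-trip formats for cohorts, ratings and results.

Dialect: comma-separated UTF-8 with a header row, ``.`` decimal separator
and empty cells for missing values.  A cohort is stored as three tables:

``findings.csv``
    Long format, columns ``patient_id, field, sign, value`` with at most one
    row per (patient, field, sign).  ``field`` is one of the 12 lung-field
    codes, or ``left``/``right`` for the per-hemithorax sign
    ``pleural_fluid_mm``.  Major-consolidation sizes are serialized as a
    ``;``-joined list in the value cell.
``patients.csv``
    One row per patient with the covariates (age, group, PFTs, microbiology).
``radiograph.csv``
    Long format ``patient_id, item_type, item, grade`` for the modified
    Chrispin-Norman items (written only when any patient has them).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .findings import (
    LungField,
    PathogenStatus,
    PatientRecord,
    PleuralFluid,
    PleuralSeverity,
    RadiographItems,
    empty_findings,
    validate_record,
)

FINDING_SIGNS = (
    "b_line_count",
    "confluent_b",
    "i_lines",
    "z_lines",
    "am_line_count",
    "small_consolidation_count",
    "major_consolidation_sizes_mm",
    "pleural_line",
)


class CohortReadError(ValueError):
    """Raised in strict mode when a cohort file fails validation."""


def write_cohort(cohort: Sequence[PatientRecord], directory: "str | Path") -> Dict[str, Path]:
    """Write a cohort to ``findings.csv``, ``patients.csv`` (and
    ``radiograph.csv`` when present) under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    finding_rows: List[Tuple[str, str, str, str]] = []
    patient_rows: List[Dict[str, object]] = []
    radiograph_rows: List[Tuple[str, str, str, int]] = []

    for rec in cohort:
        for fld in LungField:
            ff = rec.findings[fld]
            rows = [
                ("b_line_count", str(ff.b_line_count)),
                ("confluent_b", str(int(ff.confluent_b))),
                ("i_lines", str(int(ff.i_lines))),
                ("z_lines", str(int(ff.z_lines))),
                ("am_line_count", str(ff.am_line_count)),
                ("small_consolidation_count", str(ff.small_consolidation_count)),
                (
                    "major_consolidation_sizes_mm",
                    ";".join(f"{s:g}" for s in ff.major_consolidation_sizes_mm),
                ),
                ("pleural_line", ff.pleural_line.value),
            ]
            finding_rows += [(rec.patient_id, fld.value, s, v) for s, v in rows]
        for pf in sorted(rec.pleural_fluid, key=lambda p: p.side):
            finding_rows.append(
                (rec.patient_id, pf.side, "pleural_fluid_mm", f"{pf.layer_thickness_mm:g}")
            )
        patient_rows.append(
            {
                "patient_id": rec.patient_id,
                "age_years": rec.age_years,
                "group": rec.group,
                "fev1_pct_pred": rec.fev1_pct_pred,
                "fvc_pct_pred": rec.fvc_pct_pred,
                "lci": rec.lci,
                "cf_pathogen_status": rec.cf_pathogen_status.value,
                "fungal_infection": int(rec.fungal_infection),
            }
        )
        if rec.radiograph is not None:
            for name, grade in sorted(rec.radiograph.chest_configuration.items()):
                radiograph_rows.append((rec.patient_id, "chest_configuration", name, grade))
            for key, grade in sorted(rec.radiograph.zone_shadows.items()):
                radiograph_rows.append((rec.patient_id, "zone_shadow", key, grade))

    paths = {}
    paths["findings"] = directory / "findings.csv"
    pd.DataFrame(finding_rows, columns=["patient_id", "field", "sign", "value"]).to_csv(
        paths["findings"], index=False
    )
    paths["patients"] = directory / "patients.csv"
    pd.DataFrame(patient_rows).to_csv(paths["patients"], index=False)
    if radiograph_rows:
        paths["radiograph"] = directory / "radiograph.csv"
        pd.DataFrame(
            radiograph_rows, columns=["patient_id", "item_type", "item", "grade"]
        ).to_csv(paths["radiograph"], index=False)
    return paths


def read_cohort(directory: "str | Path", strict: bool = True) -> List[PatientRecord]:
    """Read a cohort written by :func:`write_cohort`.

    Every record is validated; in strict mode any violation (missing lung
    field, duplicate (patient, field, sign) triple, unknown enum value,
    out-of-range number) raises :class:`CohortReadError` naming the
    offender, while lenient mode skips bad records and keeps a count in the
    returned list's ``skipped`` attribute-free log (reported via logging).
    """
    directory = Path(directory)
    findings_path = directory / "findings.csv"
    patients_path = directory / "patients.csv"
    for p in (findings_path, patients_path):
        if not p.exists():
            raise FileNotFoundError(p)

    fdf = pd.read_csv(findings_path, dtype=str, keep_default_na=False)
    _require_columns(fdf, ["patient_id", "field", "sign", "value"], findings_path)
    pdf = pd.read_csv(patients_path)
    _require_columns(pdf, ["patient_id", "age_years", "group"], patients_path)

    dup = fdf.duplicated(subset=["patient_id", "field", "sign"], keep=False)
    if dup.any():
        first = fdf[dup].iloc[0]
        raise CohortReadError(
            "duplicate (patient, field, sign) triple: "
            f"({first.patient_id}, {first.field}, {first.sign})"
        )

    rdf = None
    radiograph_path = directory / "radiograph.csv"
    if radiograph_path.exists():
        rdf = pd.read_csv(radiograph_path)
        _require_columns(rdf, ["patient_id", "item_type", "item", "grade"], radiograph_path)

    records: List[PatientRecord] = []
    errors: List[str] = []
    for _, prow in pdf.iterrows():
        pid = str(prow.patient_id)
        sub = fdf[fdf.patient_id == pid]
        try:
            record = _build_record(pid, prow, sub, rdf)
        except (ValueError, KeyError) as exc:
            errors.append(f"{pid}: {exc}")
            continue
        violations = validate_record(record)
        if violations:
            errors.append(f"{pid}: " + "; ".join(violations))
            continue
        records.append(record)
    if errors and strict:
        raise CohortReadError("; ".join(errors))
    return records


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CohortReadError(f"{path}: missing columns {missing}")


def _build_record(pid: str, prow, sub: pd.DataFrame, rdf) -> PatientRecord:
    findings = empty_findings()
    fluid = {"left": 0.0, "right": 0.0}
    for _, row in sub.iterrows():
        sign, value = row.sign, row.value
        if sign == "pleural_fluid_mm":
            if row.field not in fluid:
                raise ValueError(f"pleural fluid side must be left/right, got {row.field!r}")
            fluid[row.field] = float(value)
            continue
        fld = LungField(row.field)
        ff = findings[fld]
        if sign in ("b_line_count", "am_line_count", "small_consolidation_count"):
            setattr(ff, sign, int(value))
        elif sign in ("confluent_b", "i_lines", "z_lines"):
            setattr(ff, sign, bool(int(value)))
        elif sign == "pleural_line":
            ff.pleural_line = PleuralSeverity(value)
        elif sign == "major_consolidation_sizes_mm":
            ff.major_consolidation_sizes_mm = (
                [float(v) for v in str(value).split(";") if v] if value else []
            )
        else:
            raise ValueError(f"unknown sign {sign!r}")

    radiograph: Optional[RadiographItems] = None
    if rdf is not None:
        rsub = rdf[rdf.patient_id == pid]
        if len(rsub):
            chest = {
                str(r.item): int(r.grade)
                for r in rsub.itertuples()
                if r.item_type == "chest_configuration"
            }
            zones = {
                str(r.item): int(r.grade)
                for r in rsub.itertuples()
                if r.item_type == "zone_shadow"
            }
            radiograph = RadiographItems(chest_configuration=chest, zone_shadows=zones)

    def opt(name):
        v = prow.get(name)
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

    return PatientRecord(
        patient_id=pid,
        age_years=float(prow.age_years),
        group=str(prow.group),
        findings=findings,
        pleural_fluid=[
            PleuralFluid(side="left", layer_thickness_mm=fluid["left"]),
            PleuralFluid(side="right", layer_thickness_mm=fluid["right"]),
        ],
        radiograph=radiograph,
        fev1_pct_pred=opt("fev1_pct_pred"),
        fvc_pct_pred=opt("fvc_pct_pred"),
        lci=opt("lci"),
        cf_pathogen_status=PathogenStatus(str(prow.get("cf_pathogen_status", "none"))),
        fungal_infection=bool(int(prow.get("fungal_infection", 0) or 0)),
    )


# ---------------------------------------------------------------------------
# Ratings and results


def write_ratings(
    ratings: Dict[str, Tuple[np.ndarray, np.ndarray]],
    path: "str | Path",
    patient_ids: Optional[Sequence[str]] = None,
) -> Path:
    """Write paired per-sign binary ratings as long CSV
    (patient_id, unit, sign, rater, value)."""
    path = Path(path)
    rows = []
    for sign, (r1, r2) in ratings.items():
        units = (
            ["left", "right"]
            if r1.shape[1] == 2
            else [f.value for f in LungField]
        )
        n = r1.shape[0]
        ids = patient_ids if patient_ids is not None else [f"p{i+1:04d}" for i in range(n)]
        for rater, mat in ((1, r1), (2, r2)):
            for i in range(n):
                for j, unit in enumerate(units):
                    rows.append((ids[i], unit, sign, rater, int(mat[i, j])))
    pd.DataFrame(rows, columns=["patient_id", "unit", "sign", "rater", "value"]).to_csv(
        path, index=False
    )
    return path


def read_ratings(path: "str | Path") -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Read paired ratings written by :func:`write_ratings`."""
    df = pd.read_csv(path)
    _require_columns(df, ["patient_id", "unit", "sign", "rater", "value"], path)
    if not df.value.isin((0, 1)).all():
        raise CohortReadError(f"{path}: ratings must be binary 0/1")
    canonical = [f.value for f in LungField]
    out: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for sign, sdf in df.groupby("sign", sort=False):
        units = set(sdf.unit)
        order = (
            ["left", "right"] if units == {"left", "right"}
            else [u for u in canonical if u in units]
        )
        mats = []
        for rater in (1, 2):
            rdf_ = sdf[sdf.rater == rater]
            mat = rdf_.pivot(index="patient_id", columns="unit", values="value")
            mats.append(mat.sort_index().reindex(columns=order))
        if list(mats[0].index) != list(mats[1].index):
            raise CohortReadError(f"{path}: raters cover different patients for {sign}")
        out[str(sign)] = (mats[0].to_numpy(), mats[1].to_numpy())
    return out


def scores_frame(cohort: Sequence[PatientRecord], results) -> pd.DataFrame:
    """Tabulate per-patient, per-area score breakdowns with the total."""
    rows = []
    for rec, res in zip(cohort, results):
        for a in res.per_area:
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "area": a.area.value,
                    "small_consolidations": a.small_consolidations,
                    "major_consolidations": a.major_consolidations,
                    "pleural_line": a.pleural_line,
                    "am_lines": a.am_lines,
                    "b_lines": a.b_lines,
                    "b_line_bonus": a.b_line_bonus,
                    "subtotal": a.subtotal,
                    "total": res.total,
                }
            )
    return pd.DataFrame(rows)


def write_json(obj, path: "str | Path") -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path
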