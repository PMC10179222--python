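"""The CF LUS score engine and a configurable modified Chrispin-Norman score.

The CF LUS score grades five finding categories per scoring area, each on a
0/1/2 intensity scale, over 4 areas of 3 lung fields each:

========================  ===========  ==================  =========================
category                  grade 0      grade 1             grade 2
========================  ===========  ==================  =========================
small consolidations      <=1          2-3                 >=4        (area total)
major consolidations      absent       single <=40 mm      >=2, or 1 >40 mm
pleural line              absent or    present,            marked or widespread
                          minimal      not marked
Am-lines                  absent       <=2                 >=3        (area total)
B-lines                   <=3 / field  confluent or >=4    >=4 in >=2 of 3 fields
                                       in 1 of 3 fields
========================  ===========  ==================  =========================

A bonus point per area is added when B-lines are present in all three of its
fields; with the bonus the maximum total is 44 (4 areas x (5x2 + 1)).
Pleural fluid is deliberately not scored; it is reported descriptively only.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

from .findings import (
    AREA_FIELDS,
    FieldFindings,
    LungArea,
    PatientRecord,
    PleuralSeverity,
)

FIELDS_PER_AREA = 3
#: B-line count at or above which a field counts as having "numerous" B-lines.
NUMEROUS_B_THRESHOLD = 4


class BonusRule(str, enum.Enum):
    """Interpretation of the per-area B-line bonus point.

    ``any_b_in_all_fields``
        +1 when every field in the area shows at least one B-line (a field
        with >=4 B-lines also contains 1-3 of them).  Makes the printed
        maximum of 44 attainable and is the default.
    ``strict_1_to_3``
        +1 only when every field count lies in [1, 3]; incompatible with a
        nonzero base grade from counts, so the attainable maximum drops to 40.
    ``disabled``
        No bonus; maximum 40.
    """

    any_b_in_all_fields = "any_b_in_all_fields"
    strict_1_to_3 = "strict_1_to_3"
    disabled = "disabled"


@dataclass(frozen=True)
class AreaScore:
    """Per-area grade breakdown; ``subtotal`` = five grades + bonus, in [0, 11]."""

    area: LungArea
    small_consolidations: int
    major_consolidations: int
    pleural_line: int
    am_lines: int
    b_lines: int
    b_line_bonus: int
    subtotal: int


@dataclass(frozen=True)
class CFLUSResult:
    """Full CF LUS result: four area breakdowns and the 0-44 total."""

    per_area: Tuple[AreaScore, ...]
    total: int

    def area(self, code: "LungArea | str") -> AreaScore:
        code = LungArea(code)
        for a in self.per_area:
            if a.area is code:
                return a
        raise KeyError(code)


def _check_count(count: int, what: str) -> None:
    if count < 0:
        raise ValueError(f"{what} must be non-negative, got {count}")


def grade_small_consolidations(count_in_area: int) -> int:
    """Grade the area total of small (<=10 mm) consolidations: <=1 / 2-3 / >=4."""
    _check_count(count_in_area, "small-consolidation count")
    if count_in_area <= 1:
        return 0
    if count_in_area <= 3:
        return 1
    return 2


def grade_major_consolidations(sizes_mm: Sequence[float]) -> int:
    """Grade pooled major (>10 mm) consolidations: absent / single <=40 mm / >=2 or 1 >40 mm."""
    for s in sizes_mm:
        if s <= 10:
            raise ValueError(f"major consolidation size must exceed 10 mm, got {s}")
    if len(sizes_mm) == 0:
        return 0
    if len(sizes_mm) == 1 and sizes_mm[0] <= 40:
        return 1
    return 2


def grade_pleural_line(field_severities: Sequence[PleuralSeverity]) -> int:
    """Grade pleural-line abnormality over the area's 3 fields.

    2 when any field is marked, or the abnormality is widespread (at least
    "present" in >=2 of the 3 fields); 1 when exactly one field is "present";
    0 when all fields are absent or minimal.
    """
    if len(field_severities) != FIELDS_PER_AREA:
        raise ValueError(
            f"expected {FIELDS_PER_AREA} field severities, got {len(field_severities)}"
        )
    sev = [PleuralSeverity(s) for s in field_severities]
    if any(s is PleuralSeverity.marked for s in sev):
        return 2
    n_present = sum(s is PleuralSeverity.present for s in sev)
    if n_present >= 2:
        return 2
    if n_present == 1:
        return 1
    return 0


def grade_am_lines(count_in_area: int) -> int:
    """Grade the area total of Am-line artefacts: absent / <=2 / >=3."""
    _check_count(count_in_area, "Am-line count")
    if count_in_area == 0:
        return 0
    if count_in_area <= 2:
        return 1
    return 2


def grade_b_lines(
    per_field_counts: Sequence[int],
    per_field_confluent: Sequence[bool],
    bonus_rule: BonusRule = BonusRule.any_b_in_all_fields,
) -> Tuple[int, int]:
    """Grade B-line artefacts for one area and decide the bonus point.

    Base grade: 2 when >=4 B-lines appear in most of the area (at least 2 of
    its 3 fields); 1 when exactly one field has >=4 or any field shows
    confluent B-lines; 0 otherwise.  Returns ``(base, bonus)`` with the bonus
    capped at 1 per area.
    """
    if len(per_field_counts) != FIELDS_PER_AREA or len(per_field_confluent) != FIELDS_PER_AREA:
        raise ValueError(f"expected {FIELDS_PER_AREA} fields per area")
    for c in per_field_counts:
        _check_count(c, "B-line count")

    n_numerous = sum(c >= NUMEROUS_B_THRESHOLD for c in per_field_counts)
    if n_numerous >= 2:
        base = 2
    elif n_numerous == 1 or any(per_field_confluent):
        base = 1
    else:
        base = 0

    if bonus_rule is BonusRule.disabled:
        bonus = 0
    elif bonus_rule is BonusRule.strict_1_to_3:
        bonus = int(all(1 <= c <= 3 for c in per_field_counts))
    else:
        bonus = int(all(c >= 1 for c in per_field_counts))
    return base, bonus


def score_area(
    area: "LungArea | str",
    findings: Sequence[FieldFindings],
    bonus_rule: BonusRule = BonusRule.any_b_in_all_fields,
) -> AreaScore:
    """Score one area from its 3 fields' findings.

    Small-consolidation and Am-line counts are summed across the fields
    before grading; major-consolidation sizes are pooled.
    """
    area = LungArea(area)
    if len(findings) != FIELDS_PER_AREA:
        raise ValueError(f"area {area.value} needs {FIELDS_PER_AREA} fields of findings")

    g_small = grade_small_consolidations(sum(f.small_consolidation_count for f in findings))
    pooled_sizes = [s for f in findings for s in f.major_consolidation_sizes_mm]
    g_major = grade_major_consolidations(pooled_sizes)
    g_pleural = grade_pleural_line([f.pleural_line for f in findings])
    g_am = grade_am_lines(sum(f.am_line_count for f in findings))
    g_b, bonus = grade_b_lines(
        [f.b_line_count for f in findings],
        [f.confluent_b for f in findings],
        bonus_rule,
    )
    subtotal = g_small + g_major + g_pleural + g_am + g_b + bonus
    return AreaScore(
        area=area,
        small_consolidations=g_small,
        major_consolidations=g_major,
        pleural_line=g_pleural,
        am_lines=g_am,
        b_lines=g_b,
        b_line_bonus=bonus,
        subtotal=subtotal,
    )


def score_patient(
    record: PatientRecord,
    bonus_rule: BonusRule = BonusRule.any_b_in_all_fields,
) -> CFLUSResult:
    """Compute the CF LUS score (0-44) for a validated patient record."""
    per_area = []
    for area, fields in AREA_FIELDS.items():
        per_area.append(score_area(area, [record.findings[f] for f in fields], bonus_rule))
    return CFLUSResult(per_area=tuple(per_area), total=sum(a.subtotal for a in per_area))


def max_total(bonus_rule: BonusRule = BonusRule.any_b_in_all_fields) -> int:
    """Maximum attainable total under a bonus interpretation, by enumeration.

    Enumerates per-field B-line counts (0..5 saturates every threshold) and
    confluence flags to find the best attainable B-line-plus-bonus value;
    the other four categories each reach grade 2 independently.
    """
    best_b = 0
    for counts in itertools.product(range(6), repeat=FIELDS_PER_AREA):
        for confl in itertools.product((False, True), repeat=FIELDS_PER_AREA):
            base, bonus = grade_b_lines(list(counts), list(confl), bonus_rule)
            best_b = max(best_b, base + bonus)
    per_area_max = 4 * 2 + best_b
    return 4 * per_area_max


# ---------------------------------------------------------------------------
# Modified Chrispin-Norman radiographic score


ZONES = ("upper-right", "lower-right", "upper-left", "lower-left")
SHADOW_TYPES = ("bronchial_line", "mottled", "ring", "large_soft")
DEFAULT_CHEST_CONFIG_ITEMS = ("sternal_bowing", "kyphosis", "diaphragm_depression")

#: Shadow types read as consistent with bronchiectasis on the radiograph.
BRONCHIECTASIS_SHADOWS = ("bronchial_line", "ring")


@dataclass(frozen=True)
class CNConfig:
    """Item set of a modified Chrispin-Norman score; every item grades 0/1/2.

    The default set (3 chest-configuration items + 4 zones x 4 shadow types,
    maximum 38) is an assumption documented in the methods note; any item
    set summing 0/1/2 grades is accepted.
    """

    chest_config_items: Tuple[str, ...] = DEFAULT_CHEST_CONFIG_ITEMS
    zones: Tuple[str, ...] = ZONES
    shadow_types: Tuple[str, ...] = SHADOW_TYPES

    @property
    def max_score(self) -> int:
        return 2 * (len(self.chest_config_items) + len(self.zones) * len(self.shadow_types))


@dataclass(frozen=True)
class CNResult:
    """Modified Chrispin-Norman total with per-item breakdown."""

    total: int
    per_item: Dict[str, int]
    max_score: int


def score_chrispin_norman(items, config: CNConfig | None = None) -> CNResult:
    """Sum the configured radiograph item grades.

    ``items`` is a :class:`~cflus.findings.RadiographItems`; missing items
    and grades outside {0,1,2} raise ``ValueError``.
    """
    config = config or CNConfig()
    per_item: Dict[str, int] = {}

    for name in config.chest_config_items:
        if name not in items.chest_configuration:
            raise ValueError(f"missing chest-configuration item: {name}")
        per_item[name] = _check_grade(items.chest_configuration[name], name)
    for zone in config.zones:
        for shadow in config.shadow_types:
            key = f"{zone}:{shadow}"
            if key not in items.zone_shadows:
                raise ValueError(f"missing zone-shadow item: {key}")
            per_item[key] = _check_grade(items.zone_shadows[key], key)

    total = sum(per_item.values())
    return CNResult(total=total, per_item=per_item, max_score=config.max_score)


def _check_grade(grade: int, name: str) -> int:
    if grade not in (0, 1, 2):
        raise ValueError(f"item {name}: grade {grade} not in {{0,1,2}}")
    return grade


def bronchiectasis_subscore(items, config: CNConfig | None = None) -> int:
    """Sum of zone grades for shadow types consistent with bronchiectasis
    (bronchial line shadows and ring shadows)."""
    config = config or CNConfig()
    return sum(
        _check_grade(items.zone_shadows.get(f"{zone}:{shadow}", 0), f"{zone}:{shadow}")
        for zone in config.zones
        for shadow in BRONCHIECTASIS_SHADOWS
        if shadow in config.shadow_types
    )
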