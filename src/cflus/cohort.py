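"""Cohort-level descriptive and inferential analysis.

Reproduces the shape of the study-style outputs: sign-prevalence tables with
95% confidence intervals, Pearson correlations with least-squares regression
lines, two-group and multi-group comparisons, and 2x2 associations by
Fisher's exact test, assembled into a severity-vs-covariates report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .agreement import ContingencyTable2x2, guilford_band
from .findings import LungField, PatientRecord
from .scoring import NUMEROUS_B_THRESHOLD, BonusRule, score_patient

# ---------------------------------------------------------------------------
# Sign predicates: "patient shows the sign in at least one lung field"

SIGN_PREDICATES: Dict[str, Callable[[PatientRecord], bool]] = {
    "i_lines": lambda r: any(f.i_lines for f in r.findings.values()),
    "z_lines": lambda r: any(f.z_lines for f in r.findings.values()),
    "single_b_lines": lambda r: any(f.b_line_count >= 1 for f in r.findings.values()),
    "numerous_b_lines": lambda r: any(
        f.b_line_count >= NUMEROUS_B_THRESHOLD for f in r.findings.values()
    ),
    "confluent_b_lines": lambda r: any(f.confluent_b for f in r.findings.values()),
    "am_lines": lambda r: any(f.am_line_count >= 1 for f in r.findings.values()),
    # any abnormality counts for prevalence, including "minimal" ones that
    # grade 0 on the score (controls typically show only minimal changes)
    "pleural_line_abnormalities": lambda r: any(
        f.pleural_line.rank >= 1 for f in r.findings.values()
    ),
    "small_consolidations": lambda r: any(
        f.small_consolidation_count >= 1 for f in r.findings.values()
    ),
    "major_consolidations": lambda r: any(
        len(f.major_consolidation_sizes_mm) >= 1 for f in r.findings.values()
    ),
    "pleural_fluid": lambda r: any(pf.layer_thickness_mm > 0 for pf in r.pleural_fluid),
}

ALL_SIGNS = tuple(SIGN_PREDICATES)


def sign_present(record: PatientRecord, sign: str) -> bool:
    """Whether the patient shows ``sign`` in at least one lung field."""
    try:
        return SIGN_PREDICATES[sign](record)
    except KeyError:
        raise ValueError(f"unknown sign name: {sign!r}") from None


def sign_field_matrix(cohort: Sequence[PatientRecord], sign: str) -> np.ndarray:
    """Per-field binary presence matrix (n_patients x 12) for one sign.

    ``pleural_fluid`` is assessed per pleural cavity, giving 2 columns.
    """
    if sign == "pleural_fluid":
        return np.array(
            [
                [int(pf.layer_thickness_mm > 0) for pf in sorted(r.pleural_fluid, key=lambda p: p.side)]
                for r in cohort
            ]
        )
    per_field = {
        "i_lines": lambda f: f.i_lines,
        "z_lines": lambda f: f.z_lines,
        "single_b_lines": lambda f: f.b_line_count >= 1,
        "numerous_b_lines": lambda f: f.b_line_count >= NUMEROUS_B_THRESHOLD,
        "confluent_b_lines": lambda f: f.confluent_b,
        "am_lines": lambda f: f.am_line_count >= 1,
        "pleural_line_abnormalities": lambda f: f.pleural_line.rank >= 1,
        "small_consolidations": lambda f: f.small_consolidation_count >= 1,
        "major_consolidations": lambda f: len(f.major_consolidation_sizes_mm) >= 1,
    }
    try:
        pred = per_field[sign]
    except KeyError:
        raise ValueError(f"unknown sign name: {sign!r}") from None
    return np.array(
        [[int(pred(r.findings[fld])) for fld in LungField] for r in cohort]
    )


# ---------------------------------------------------------------------------
# Prevalence


@dataclass(frozen=True)
class PrevalenceRow:
    """Patients showing a sign: count, rounded percentage, Wilson 95% CI."""

    sign: str
    group: str
    n_with: int
    n_total: int
    pct: int
    ci_low: float
    ci_high: float


def percentage(n_with: int, n_total: int) -> int:
    """Percentage rounded to the nearest integer (halves round up)."""
    if not 0 <= n_with <= n_total:
        raise ValueError("need 0 <= n_with <= n_total")
    return int(math.floor(100 * n_with / n_total + 0.5))


def wilson_ci(
    n_with: int, n_total: int, alpha: float = 0.05, continuity: bool = False
) -> Tuple[float, float]:
    """Wilson score interval for a binomial proportion, clipped to [0, 1].

    The plain interval is the default (coverage close to nominal at cohort
    sizes in the hundreds); ``continuity=True`` gives the continuity-
    corrected variant, which is conservative.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    z = stats.norm.ppf(1 - alpha / 2)
    p = n_with / n_total
    n = n_total
    if not continuity:
        centre = p + z**2 / (2 * n)
        half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
        denom = 1 + z**2 / n
        return max(0.0, (centre - half) / denom), min(1.0, (centre + half) / denom)
    if n_with == 0:
        lo = 0.0
    else:
        lo = (
            2 * n * p + z**2 - 1 - z * math.sqrt(z**2 - 2 - 1 / n + 4 * p * (n * (1 - p) + 1))
        ) / (2 * (n + z**2))
    if n_with == n_total:
        hi = 1.0
    else:
        hi = (
            2 * n * p + z**2 + 1 + z * math.sqrt(z**2 + 2 - 1 / n + 4 * p * (n * (1 - p) - 1))
        ) / (2 * (n + z**2))
    return max(0.0, lo), min(1.0, hi)


def prevalence_table(
    cohort: Sequence[PatientRecord],
    signs: Sequence[str] = ALL_SIGNS,
    alpha: float = 0.05,
) -> List[PrevalenceRow]:
    """Per-sign, per-group prevalence rows (patients, not fields, counted)."""
    if not cohort:
        raise ValueError("cohort is empty")
    rows: List[PrevalenceRow] = []
    groups = sorted({r.group for r in cohort}, reverse=True)  # cf before control
    for sign in signs:
        for group in groups:
            members = [r for r in cohort if r.group == group]
            n_with = sum(sign_present(r, sign) for r in members)
            lo, hi = wilson_ci(n_with, len(members), alpha)
            rows.append(
                PrevalenceRow(
                    sign=sign,
                    group=group,
                    n_with=n_with,
                    n_total=len(members),
                    pct=percentage(n_with, len(members)),
                    ci_low=lo,
                    ci_high=hi,
                )
            )
    return rows


def prevalence_frame(rows: Sequence[PrevalenceRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# Correlation and regression


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with the least-squares line and R^2."""

    r: float
    p_value: float
    slope: float
    intercept: float
    r_squared: float
    n: int
    guilford_label: str
    degenerate: bool = False


def pearson_with_regression(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson's r (two-sided t-test p), OLS slope/intercept and R^2 = r^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            r=math.nan, p_value=math.nan, slope=math.nan, intercept=math.nan,
            r_squared=math.nan, n=int(x.size), guilford_label="undefined",
            degenerate=True,
        )
    lr = stats.linregress(x, y)
    r = float(lr.rvalue)
    return CorrelationResult(
        r=r,
        p_value=float(lr.pvalue),
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        r_squared=r**2,
        n=int(x.size),
        guilford_label=guilford_band(r),
    )


# ---------------------------------------------------------------------------
# Group comparisons


@dataclass(frozen=True)
class GroupComparison:
    """Two- or k-group location comparison with group means and SDs."""

    groups: Tuple[str, ...]
    means: Tuple[float, ...]
    sds: Tuple[float, ...]
    ns: Tuple[int, ...]
    test_used: str  # mann_whitney | t_test | kruskal_wallis
    statistic: float
    p_value: float


def compare_two_groups(
    values: Sequence[float],
    labels: Sequence,
    policy: str = "auto",
    shapiro_alpha: float = 0.05,
) -> GroupComparison:
    """Compare the location of a quantity between two groups.

    ``policy="auto"`` runs Shapiro-Wilk on each group and uses Student's
    t-test when both pass at ``shapiro_alpha``, the Mann-Whitney-Wilcoxon
    rank-sum test otherwise; ``"mww"`` and ``"t"`` force a test.
    """
    if policy not in ("auto", "mww", "t"):
        raise ValueError("policy must be auto, mww or t")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()), key=str)
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(uniq)}")
    samples = [values[labels == g] for g in uniq]
    for g, s in zip(uniq, samples):
        if s.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")

    if policy == "auto":
        normal = all(
            s.size >= 3 and np.ptp(s) > 0 and stats.shapiro(s).pvalue > shapiro_alpha
            for s in samples
        )
        policy = "t" if normal else "mww"
    if policy == "t":
        res = stats.ttest_ind(samples[0], samples[1])
        test_used = "t_test"
    else:
        res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        test_used = "mann_whitney"
    return GroupComparison(
        groups=tuple(str(g) for g in uniq),
        means=tuple(float(s.mean()) for s in samples),
        sds=tuple(float(s.std(ddof=1)) for s in samples),
        ns=tuple(int(s.size) for s in samples),
        test_used=test_used,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def kruskal_wallis_by_category(values: Sequence[float], category: Sequence) -> GroupComparison:
    """Kruskal-Wallis H test (tie-corrected) across k >= 3 categories."""
    values = np.asarray(values, dtype=float)
    category = np.asarray(category)
    uniq = sorted(set(category.tolist()), key=str)
    if len(uniq) < 3:
        raise ValueError("need at least 3 categories; use compare_two_groups for 2")
    samples = [values[category == g] for g in uniq]
    for g, s in zip(uniq, samples):
        if s.size == 0:
            raise ValueError(f"category {g!r} is empty")
    h, p = stats.kruskal(*samples)
    return GroupComparison(
        groups=tuple(str(g) for g in uniq),
        means=tuple(float(s.mean()) for s in samples),
        sds=tuple(float(s.std(ddof=1)) if s.size > 1 else math.nan for s in samples),
        ns=tuple(int(s.size) for s in samples),
        test_used="kruskal_wallis",
        statistic=float(h),
        p_value=float(p),
    )


# ---------------------------------------------------------------------------
# 2x2 associations


@dataclass(frozen=True)
class AssociationResult:
    """Fisher's exact test on a 2x2 table, with the conditional odds ratio."""

    table: ContingencyTable2x2
    fisher_p: float
    odds_ratio: float  # math.inf when a zero cell makes it infinite
    convention: str = "minlike"


def fisher_association(
    table: ContingencyTable2x2, convention: str = "minlike"
) -> AssociationResult:
    """Two-sided Fisher's exact test by hypergeometric enumeration.

    ``convention="minlike"`` (default) sums all tables no more likely than
    the observed one; ``"doubling"`` doubles the smaller one-sided p
    (capped at 1).  The odds ratio is the conditional MLE; a zero cell that
    makes it infinite is reported as ``math.inf``.
    """
    arr = table.as_array()
    if convention == "minlike":
        _, p = stats.fisher_exact(arr, alternative="two-sided")
    elif convention == "doubling":
        _, p_less = stats.fisher_exact(arr, alternative="less")
        _, p_greater = stats.fisher_exact(arr, alternative="greater")
        p = min(1.0, 2 * min(p_less, p_greater))
    else:
        raise ValueError("convention must be 'minlike' or 'doubling'")
    orr = stats.contingency.odds_ratio(arr, kind="conditional").statistic
    return AssociationResult(
        table=table, fisher_p=float(p), odds_ratio=float(orr), convention=convention
    )


# ---------------------------------------------------------------------------
# Report bundle


@dataclass
class CovariateReport:
    """Severity score against covariates: correlations, group tests, notes."""

    n_patients: int
    correlations: Dict[str, CorrelationResult] = field(default_factory=dict)
    comparisons: Dict[str, GroupComparison] = field(default_factory=dict)
    unavailable: List[str] = field(default_factory=list)
    n_missing: Dict[str, int] = field(default_factory=dict)


def score_vs_covariates_report(
    cohort: Sequence[PatientRecord],
    bonus_rule: BonusRule = BonusRule.any_b_in_all_fields,
    policy: str = "auto",
) -> CovariateReport:
    """Correlate the severity score with each available covariate.

    Continuous covariates (age, radiographic score, FEV1/FVC %predicted,
    LCI) yield Pearson/regression results; binary covariates (CF-pathogen
    and fungal status) yield two-group comparisons, and the pathogen
    subtype yields a Kruskal-Wallis comparison when >= 3 subtypes occur.
    Patients missing a covariate are skipped for that covariate, with the
    skipped count logged; a covariate absent from every patient is listed
    as unavailable.  No multiplicity adjustment is applied: raw p-values.
    """
    from .scoring import score_chrispin_norman

    cf = [r for r in cohort if r.group == "cf"]
    if not cf:
        raise ValueError("no CF patients to analyse")
    totals = np.array([score_patient(r, bonus_rule).total for r in cf], dtype=float)
    report = CovariateReport(n_patients=len(cf))

    def continuous(name: str, getter) -> None:
        pairs = [(t, getter(r)) for t, r in zip(totals, cf) if getter(r) is not None]
        report.n_missing[name] = len(cf) - len(pairs)
        if len(pairs) < 3:
            report.unavailable.append(name)
            return
        score_v = np.array([p[0] for p in pairs])
        cov_v = np.array([p[1] for p in pairs], dtype=float)
        report.correlations[name] = pearson_with_regression(cov_v, score_v)

    continuous("age_years", lambda r: r.age_years)
    continuous(
        "chrispin_norman",
        lambda r: score_chrispin_norman(r.radiograph).total if r.radiograph else None,
    )
    continuous("fev1_pct_pred", lambda r: r.fev1_pct_pred)
    continuous("fvc_pct_pred", lambda r: r.fvc_pct_pred)
    continuous("lci", lambda r: r.lci)

    # binary covariates: pathogen yes/no, fungal yes/no
    for name, getter in (
        ("cf_pathogens", lambda r: r.has_pathogen()),
        ("fungal_infection", lambda r: r.fungal_infection),
    ):
        flags = np.array([getter(r) for r in cf])
        if 2 <= flags.sum() <= len(cf) - 2:
            report.comparisons[name] = compare_two_groups(totals, flags, policy=policy)
        else:
            report.unavailable.append(name)

    # pathogen subtype among infected patients
    infected = [(t, r.cf_pathogen_status.value) for t, r in zip(totals, cf) if r.has_pathogen()]
    subtypes = {s for _, s in infected}
    if len(subtypes) >= 3 and all(
        sum(s == u for _, s in infected) >= 1 for u in subtypes
    ):
        report.comparisons["pathogen_subtype"] = kruskal_wallis_by_category(
            [t for t, _ in infected], [s for _, s in infected]
        )
    else:
        report.unavailable.append("pathogen_subtype")
    return report
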