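"""Synthetic cohorts and paired-observer readings for the scoring pipeline.

No patient-level data are available for this kind of study, so the package
ships a generator that emulates the statistical structure the analyses
assume: a paediatric cohort with a latent lung-disease severity that rises
with age; per-sign patient prevalences hit exactly (up to integer rounding) by
rank-thresholding Gaussian-copula draws, so the marginal is the configured
target while sicker patients carry more signs; an apico-basal field
gradient (lower > middle > upper fields); severity-linked covariates
(radiographic score, FEV1/FVC, LCI, microbiology); and a second observer
who differs from the first by independent symmetric flips at a per-sign
rate eps, giving the closed-form calibration PABAK = 1 - 2*eps.

The generator is a stand-in calibrated to published marginals and
correlation magnitudes, not a model of any real data-generating process.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .findings import (
    LungField,
    PathogenStatus,
    PatientRecord,
    PleuralFluid,
    PleuralSeverity,
    RadiographItems,
    empty_findings,
)
from .scoring import CNConfig, NUMEROUS_B_THRESHOLD

# Rows of the chest wall, used for the apico-basal gradient.
_FIELD_ROW = {f: f.value[1] for f in LungField}  # 'U' | 'M' | 'L'
_FIELD_SURFACE = {f: f.value[0] for f in LungField}  # 'a' | 'p'

#: Patient-level sign prevalences of a clinically stable paediatric CF
#: cohort (study-like defaults).
CF_PREVALENCES: Dict[str, float] = {
    "i_lines": 123 / 131,
    "z_lines": 108 / 131,
    "single_b_lines": 130 / 131,
    "numerous_b_lines": 36 / 131,
    "confluent_b_lines": 7 / 131,
    "am_lines": 57 / 131,
    "pleural_line_abnormalities": 95 / 131,
    "small_consolidations": 84 / 131,
    "major_consolidations": 38 / 131,
    "pleural_fluid": 32 / 131,
}

#: Healthy-control prevalences: no numerous/confluent B-lines, no Am-lines,
#: no major consolidations; remaining signs sparse and minimal.
CONTROL_PREVALENCES: Dict[str, float] = {
    "i_lines": 17 / 32,
    "z_lines": 15 / 32,
    "single_b_lines": 23 / 32,
    "numerous_b_lines": 0.0,
    "confluent_b_lines": 0.0,
    "am_lines": 0.0,
    "pleural_line_abnormalities": 5 / 32,
    "small_consolidations": 2 / 32,
    "major_consolidations": 0.0,
    "pleural_fluid": 3 / 32,
}

#: Copula loading of each sign's presence on the latent severity.  Signs of
#: advanced disease (numerous B-lines, Am-lines, major consolidations,
#: fungal-linked findings) load strongest.
DEFAULT_SIGN_LOADINGS: Dict[str, float] = {
    "i_lines": 0.45,
    "z_lines": 0.35,
    "single_b_lines": 0.50,
    "numerous_b_lines": 0.85,
    "confluent_b_lines": 0.80,
    "am_lines": 0.85,
    "pleural_line_abnormalities": 0.75,
    "small_consolidations": 0.55,
    "major_consolidations": 0.85,
    "pleural_fluid": 0.60,
}

#: Relative chance that an affected field lies in each row (apico-basal
#: gradient: lower > middle > upper).
DEFAULT_ROW_WEIGHTS: Dict[str, float] = {"U": 1.0, "M": 2.0, "L": 4.0}

#: Default per-sign symmetric flip rates for the second observer, chosen so
#: PABAK = 1 - 2*eps lands at the agreement levels typical of a standardised
#: two-sonographer protocol (very good for most signs, weaker for Z-lines).
DEFAULT_FLIP_RATES: Dict[str, float] = {
    "i_lines": 0.20,
    "z_lines": 0.33,
    "single_b_lines": 0.195,
    "numerous_b_lines": 0.025,
    "am_lines": 0.08,
    "pleural_line_abnormalities": 0.215,
    "small_consolidations": 0.08,
    "major_consolidations": 0.03,
    "pleural_fluid": 0.095,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameterization of a synthetic cohort.

    ``age_severity_weight`` is the correlation between the (normal-scores
    transformed) age and the standard-normal latent severity; together with
    the sign loadings it sets the score-age correlation (the study-like
    default targets r ~ 0.7).  Prevalences are patient-level targets hit
    exactly up to integer rounding.
    """

    n_patients: int = 131
    group: str = "cf"
    age_min: float = 0.1
    age_max: float = 18.0
    # Beta(a, b) shape of (age - min)/(max - min); (1.5, 2.2) puts the
    # median near 7 years.
    age_beta: Tuple[float, float] = (1.5, 2.2)
    age_severity_weight: float = 0.85
    prevalences: Optional[Dict[str, float]] = None
    sign_loadings: Optional[Dict[str, float]] = None
    row_weights: Optional[Dict[str, float]] = None
    # mean counts (per affected field) of the truncated-Poisson count models
    b_line_rate: float = 0.8
    am_line_rate: float = 0.8
    small_consolidation_rate: float = 0.7
    # covariate links (cf group only)
    with_radiograph: bool = True
    with_pft: bool = True
    radiograph_missing: float = 1 - 83 / 131
    spirometry_missing: float = 1 - 77 / 131
    mbnw_missing: float = 1 - 64 / 131
    pathogen_prevalence: float = 63 / 131
    pathogen_loading: float = 0.70
    fungal_prevalence: float = 12 / 131
    fungal_loading: float = 0.85
    seed: int = 0

    def resolved_prevalences(self) -> Dict[str, float]:
        if self.prevalences is not None:
            prevs = dict(self.prevalences)
        else:
            prevs = dict(CF_PREVALENCES if self.group == "cf" else CONTROL_PREVALENCES)
        for name, p in prevs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence {name}={p} outside [0, 1]")
        return prevs

    def __post_init__(self):
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.group not in ("cf", "control"):
            raise ValueError("group must be 'cf' or 'control'")
        if not 0.0 <= self.age_severity_weight <= 1.0:
            raise ValueError("age_severity_weight must lie in [0, 1]")


@dataclass(frozen=True)
class ObserverNoiseConfig:
    """Second-observer noise: per-sign symmetric flip rates eps in [0, 0.5]
    for binary field presence, plus +/-1 count jitter for graded items."""

    flip_rates: Optional[Dict[str, float]] = None
    count_jitter_prob: float = 0.15
    seed: int = 1

    def resolved_flip_rates(self) -> Dict[str, float]:
        rates = dict(DEFAULT_FLIP_RATES)
        if self.flip_rates:
            rates.update(self.flip_rates)
        for name, eps in rates.items():
            if not 0.0 <= eps <= 0.5:
                raise ValueError(f"flip rate {name}={eps} outside [0, 0.5]")
        return rates


def calibrate_flip_rate(target_pabak: float) -> float:
    """Flip rate achieving an expected PABAK under symmetric one-rater flips.

    E[p_o] = 1 - eps exactly, so PABAK = 1 - 2*eps and eps = (1 - target)/2.
    Targets below 0 are unreachable with eps <= 1/2.
    """
    if not 0.0 <= target_pabak <= 1.0:
        raise ValueError(f"target PABAK {target_pabak} unreachable under symmetric flips")
    return (1.0 - target_pabak) / 2.0


# ---------------------------------------------------------------------------
# Cohort generation


def _correlated_uniform(rng, z_anchor: np.ndarray, rho: float) -> np.ndarray:
    """Uniform(0,1) variates with Gaussian-copula correlation rho to z_anchor."""
    z = rho * z_anchor + np.sqrt(1 - rho**2) * rng.standard_normal(z_anchor.size)
    return stats.norm.cdf(z)


def _choose_fields(
    rng, n_fields: int, row_weights: Dict[str, float],
    anterior_bias: float = 1.0, candidates: Sequence[LungField] = tuple(LungField),
) -> List[LungField]:
    """Sample affected fields without replacement, weighted by the
    apico-basal row gradient and an optional anterior-surface bias."""
    cand = list(candidates)
    w = np.array(
        [
            row_weights[_FIELD_ROW[f]]
            * (anterior_bias if _FIELD_SURFACE[f] == "a" else 1.0)
            for f in cand
        ]
    )
    w = w / w.sum()
    n = min(n_fields, len(cand))
    idx = rng.choice(len(cand), size=n, replace=False, p=w)
    return [cand[i] for i in idx]


def _n_affected(rng, z_sev: float, max_fields: int = 12) -> int:
    """Number of affected fields given presence: grows with severity."""
    p = stats.norm.cdf(0.35 * z_sev - 0.9)
    return 1 + rng.binomial(max_fields - 1, p)


def generate_cohort(config: GeneratorConfig) -> List[PatientRecord]:
    """Draw a synthetic cohort of validated patient records.

    Deterministic given the config (including its seed).  Control cohorts
    never show numerous or confluent B-lines, Am-lines or major
    consolidations, and their remaining findings are minimal.
    """
    rng = np.random.default_rng(config.seed)
    prevs = config.resolved_prevalences()
    loadings = dict(DEFAULT_SIGN_LOADINGS)
    if config.sign_loadings:
        loadings.update(config.sign_loadings)
    row_w = dict(config.row_weights or DEFAULT_ROW_WEIGHTS)

    n = config.n_patients
    records: List[PatientRecord] = []
    if n == 0:
        return records

    a, b = config.age_beta
    age_frac = rng.beta(a, b, size=n)
    ages = config.age_min + (config.age_max - config.age_min) * age_frac
    # normal-scores transform of age (exactly standard normal marginally)
    z_age = stats.norm.ppf(stats.beta.cdf(age_frac, a, b))
    w = config.age_severity_weight
    z_sev = w * z_age + np.sqrt(1 - w**2) * rng.standard_normal(n)

    # Rank-threshold the copula uniforms: exactly round(p*n) patients carry
    # each sign (marginals exact up to integer rounding) and the severity
    # linkage enters through the correlated ranks.
    present: Dict[str, np.ndarray] = {}
    uniforms: Dict[str, np.ndarray] = {}
    for sign, p in prevs.items():
        u = _correlated_uniform(rng, z_sev, loadings[sign])
        uniforms[sign] = u
        k = int(round(p * n))
        pres = np.zeros(n, dtype=bool)
        if k > 0:
            pres[np.argsort(u)[n - k:]] = True
        present[sign] = pres

    # "single B-lines" means >= 1 B-line and therefore nests the numerous and
    # confluent patients; hit its marginal by topping up the non-nested
    # patients with the highest severity-linked draws.
    nested = present["numerous_b_lines"] | present["confluent_b_lines"]
    target = prevs["single_b_lines"] * n
    shortfall = int(round(target - nested.sum()))
    single = nested.copy()
    if shortfall > 0:
        candidates = np.flatnonzero(~nested)
        order = candidates[np.argsort(uniforms["single_b_lines"][candidates])]
        single[order[-shortfall:]] = True
    present["single_b_lines"] = single

    is_control = config.group == "control"
    for i in range(n):
        findings = empty_findings()
        zs = float(z_sev[i])

        def affected(anterior_bias: float = 1.0, cap: int = 12):
            nf = min(_n_affected(rng, zs), cap)
            return _choose_fields(rng, nf, row_w, anterior_bias)

        if present["i_lines"][i]:
            for f in affected():
                findings[f].i_lines = True
        if present["z_lines"][i]:
            for f in affected():
                findings[f].z_lines = True

        if present["single_b_lines"][i]:
            fields = affected()
            if is_control:
                # controls: single B-lines only in middle/lower fields
                fields = [f for f in fields if _FIELD_ROW[f] != "U"] or [LungField.aLL]
            for f in fields:
                findings[f].b_line_count = 1 + min(
                    rng.poisson(config.b_line_rate), 2
                )
        if present["numerous_b_lines"][i]:
            # numerous B-lines sit mainly basally
            for f in _choose_fields(rng, 1 + rng.binomial(3, 0.4), {"U": 0.5, "M": 1.5, "L": 4.0}):
                findings[f].b_line_count = NUMEROUS_B_THRESHOLD + rng.poisson(1.2)
        if present["confluent_b_lines"][i]:
            for f in _choose_fields(rng, 1 + rng.binomial(1, 0.3), row_w):
                findings[f].confluent_b = True
                findings[f].b_line_count = max(findings[f].b_line_count, 1)

        if present["am_lines"][i]:
            for f in affected(cap=6):
                findings[f].am_line_count = 1 + rng.poisson(config.am_line_rate)

        if present["pleural_line_abnormalities"][i]:
            fields = affected()
            if is_control:
                for f in fields[:2]:
                    findings[f].pleural_line = PleuralSeverity.minimal
            else:
                p_marked = stats.norm.cdf(0.8 * zs - 1.1)
                for f in fields:
                    u = rng.random()
                    if u < p_marked:
                        findings[f].pleural_line = PleuralSeverity.marked
                    elif u < 0.75:
                        findings[f].pleural_line = PleuralSeverity.present
                    else:
                        findings[f].pleural_line = PleuralSeverity.minimal

        if present["small_consolidations"][i]:
            bias = 2.0  # anterior-dominant
            fields = affected(anterior_bias=bias, cap=8)
            if is_control:
                fields = fields[:2]
            for f in fields:
                findings[f].small_consolidation_count = (
                    1 if is_control else 1 + rng.poisson(config.small_consolidation_rate)
                )

        if present["major_consolidations"][i]:
            for f in _choose_fields(rng, 1 + rng.binomial(2, 0.3), row_w):
                n_major = 1 + rng.binomial(1, 0.25)
                sizes = np.round(11.0 + rng.gamma(2.0, 9.0, size=n_major), 1)
                findings[f].major_consolidation_sizes_mm = [float(min(s, 80.0)) for s in sizes]

        fluid = [
            PleuralFluid(side="left", layer_thickness_mm=0.0),
            PleuralFluid(side="right", layer_thickness_mm=0.0),
        ]
        if present["pleural_fluid"][i]:
            # fluid appears basally; thin layers (controls: physiological <= 2 mm)
            hi = 2.0 if is_control else 7.0
            for side_idx in ([rng.integers(2)] if rng.random() < 0.6 else [0, 1]):
                fluid[side_idx] = PleuralFluid(
                    side=fluid[side_idx].side,
                    layer_thickness_mm=float(np.round(rng.uniform(1.0, hi), 1)),
                )

        record = PatientRecord(
            patient_id=f"{'cf' if not is_control else 'hc'}{i + 1:04d}",
            age_years=float(np.round(ages[i], 2)),
            group=config.group,
            findings=findings,
            pleural_fluid=fluid,
        )
        if not is_control:
            record = _attach_covariates(record, rng, zs, config)
        records.append(record)
    return records


def _attach_covariates(record: PatientRecord, rng, zs: float, config: GeneratorConfig):
    update: Dict[str, object] = {}

    if config.with_radiograph and rng.random() >= config.radiograph_missing:
        update["radiograph"] = _radiograph_from_severity(rng, zs)

    if config.with_pft:
        if rng.random() >= config.spirometry_missing:
            fev1 = 100.0 - 10.0 * max(zs, -1.0) - 4.0 * zs**2 * (zs > 0) + rng.normal(0, 7.0)
            fvc = fev1 + rng.normal(4.0, 5.0)
            update["fev1_pct_pred"] = float(np.clip(np.round(fev1, 1), 15.0, 140.0))
            update["fvc_pct_pred"] = float(np.clip(np.round(fvc, 1), 20.0, 150.0))
        if rng.random() >= config.mbnw_missing:
            lci = 7.5 + 1.8 * zs + rng.normal(0, 1.2)
            update["lci"] = float(np.clip(np.round(lci, 2), 4.0, 22.0))

    if config.pathogen_prevalence > 0:
        u = stats.norm.cdf(
            config.pathogen_loading * zs
            + np.sqrt(1 - config.pathogen_loading**2) * rng.standard_normal()
        )
        if u > 1 - config.pathogen_prevalence:
            # subtype ordered by severity: chronic worst, first-time mildest
            v = 0.6 * zs + 0.8 * rng.standard_normal()
            if v > 0.8:
                status = PathogenStatus.chronic
            elif v > 0.3:
                status = PathogenStatus.intermittent
            elif v > -1.6:
                status = PathogenStatus.previously_reported
            else:
                status = PathogenStatus.first_time
            update["cf_pathogen_status"] = status

    if config.fungal_prevalence > 0:
        u = stats.norm.cdf(
            config.fungal_loading * zs
            + np.sqrt(1 - config.fungal_loading**2) * rng.standard_normal()
        )
        update["fungal_infection"] = bool(u > 1 - config.fungal_prevalence)

    return record.model_copy(update=update)


def _radiograph_from_severity(rng, zs: float) -> RadiographItems:
    """Radiograph item grades whose total tracks the latent severity."""
    cn_cfg = CNConfig()
    # target total on the 0-38 scale, increasing in severity
    target = int(np.clip(np.round(6.0 + 5.5 * zs + rng.normal(0, 2.0)), 0, cn_cfg.max_score))
    items = [(name, "cc") for name in cn_cfg.chest_config_items] + [
        (f"{zone}:{shadow}", "zs")
        for zone in cn_cfg.zones
        for shadow in cn_cfg.shadow_types
    ]
    order = rng.permutation(len(items))
    chest = {name: 0 for name, kind in items if kind == "cc"}
    zones = {name: 0 for name, kind in items if kind == "zs"}
    remaining = target
    for idx in order:
        if remaining <= 0:
            break
        name, kind = items[idx]
        grade = min(2, remaining) if rng.random() < 0.7 else 1
        (chest if kind == "cc" else zones)[name] = grade
        remaining -= grade
    return RadiographItems(chest_configuration=chest, zone_shadows=zones)


# ---------------------------------------------------------------------------
# Second observer

#: Signs rated per lung field by both observers (pleural fluid per cavity).
RATED_SIGNS = tuple(DEFAULT_FLIP_RATES)


def generate_second_observer(
    cohort: Sequence[PatientRecord],
    noise: ObserverNoiseConfig,
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Paired binary ratings per sign per lung field (cavity for fluid).

    Rater 1 reads the cohort's true per-field presences; rater 2 is rater 1
    with independent symmetric flips at the per-sign rate eps.  Returns
    ``{sign: (rater1_matrix, rater2_matrix)}`` with patients as rows.
    """
    from .cohort import sign_field_matrix

    rng = np.random.default_rng(noise.seed)
    rates = noise.resolved_flip_rates()
    out: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for sign in RATED_SIGNS:
        r1 = sign_field_matrix(cohort, sign)
        flips = rng.random(r1.shape) < rates[sign]
        r2 = np.where(flips, 1 - r1, r1)
        out[sign] = (r1, r2)
    return out


def second_observer_cohort(
    cohort: Sequence[PatientRecord],
    noise: ObserverNoiseConfig,
) -> List[PatientRecord]:
    """A second observer's reading as full records, for score-level agreement.

    Counts are jittered by +/-1 with ``count_jitter_prob`` (clipped at 0;
    B-line counts do not cross the numerous threshold so that sign-level
    agreement stays governed by the flip rates), the pleural-line severity
    moves one ordinal step with the same probability, and per-field binary
    presences flip at the per-sign rates.
    """
    rng = np.random.default_rng(noise.seed + 1)
    rates = noise.resolved_flip_rates()
    jit = noise.count_jitter_prob
    sev_order = [
        PleuralSeverity.absent,
        PleuralSeverity.minimal,
        PleuralSeverity.present,
        PleuralSeverity.marked,
    ]
    out: List[PatientRecord] = []
    for record in cohort:
        rec2 = record.model_copy(deep=True)
        for f, ff in rec2.findings.items():
            if rng.random() < rates["i_lines"]:
                ff.i_lines = not ff.i_lines
            if rng.random() < rates["z_lines"]:
                ff.z_lines = not ff.z_lines
            if ff.b_line_count >= 1 and rng.random() < jit:
                step = int(rng.choice((-1, 1)))
                c = ff.b_line_count + step
                if ff.b_line_count >= NUMEROUS_B_THRESHOLD:
                    c = max(c, NUMEROUS_B_THRESHOLD)
                else:
                    c = int(np.clip(c, 1, NUMEROUS_B_THRESHOLD - 1))
                ff.b_line_count = c
            if ff.am_line_count >= 1 and rng.random() < jit:
                ff.am_line_count = max(1, ff.am_line_count + int(rng.choice((-1, 1))))
            elif ff.am_line_count == 0 and rng.random() < rates["am_lines"] / 4:
                ff.am_line_count = 1
            if ff.small_consolidation_count >= 1 and rng.random() < jit:
                ff.small_consolidation_count = max(
                    0, ff.small_consolidation_count + int(rng.choice((-1, 1)))
                )
            if rng.random() < jit:
                rank = sev_order.index(ff.pleural_line)
                rank = int(np.clip(rank + rng.choice((-1, 1)), 0, 3))
                ff.pleural_line = sev_order[rank]
        out.append(rec2)
    return out
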