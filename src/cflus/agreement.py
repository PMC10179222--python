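"""Interobserver-agreement statistics for paired sonographer readings.

Binary per-field sign assessments are compared with Cohen's kappa and its
prevalence- and bias-adjusted form (PABAK = 2*p_o - 1), banded with Altman's
verbal scale; paired continuous measurements (e.g. two observers' score
totals) are compared with Lin's concordance correlation coefficient and the
slope of the simple linear regression with its confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Paired binary ratings: a = yes/yes, b = yes/no, c = no/yes, d = no/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} must be non-negative")
        if self.n < 1:
            raise ValueError("table must contain at least one pair")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def transpose(self) -> "ContingencyTable2x2":
        """Swap the raters (b and c exchange)."""
        return ContingencyTable2x2(self.a, self.c, self.b, self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def contingency_from_ratings(
    rater1: Sequence[int], rater2: Sequence[int]
) -> ContingencyTable2x2:
    """Tabulate two equal-length binary rating vectors into a 2x2 table."""
    r1 = np.asarray(rater1)
    r2 = np.asarray(rater2)
    if r1.shape != r2.shape or r1.ndim != 1 or r1.size < 1:
        raise ValueError("raters must be equal-length non-empty vectors")
    for v in (r1, r2):
        if not np.isin(v, (0, 1)).all():
            raise ValueError("ratings must be binary (0/1)")
    a = int(np.sum((r1 == 1) & (r2 == 1)))
    b = int(np.sum((r1 == 1) & (r2 == 0)))
    c = int(np.sum((r1 == 0) & (r2 == 1)))
    d = int(np.sum((r1 == 0) & (r2 == 0)))
    return ContingencyTable2x2(a, b, c, d)


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with observed/chance agreement, PABAK and the Altman band.

    ``kappa`` is ``None`` (with ``degenerate=True``) when chance agreement
    p_e = 1, i.e. both raters are constant and the ratio is undefined.
    """

    po: float
    pe: float
    kappa: Optional[float]
    pabak: float
    band: Optional[str]
    degenerate: bool = False


def cohens_kappa(table: ContingencyTable2x2) -> KappaResult:
    """Cohen's kappa for a 2x2 table of paired binary ratings.

    p_o = (a+d)/n, p_e = ((a+b)(a+c) + (c+d)(b+d)) / n^2,
    kappa = (p_o - p_e) / (1 - p_e).  A table in which both raters are
    constant has p_e = 1 and is flagged degenerate instead of dividing by 0.
    """
    a, b, c, d, n = table.a, table.b, table.c, table.d, table.n
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    pab = 2 * po - 1
    if math.isclose(pe, 1.0):
        return KappaResult(po=po, pe=pe, kappa=None, pabak=pab, band=None, degenerate=True)
    kappa = (po - pe) / (1 - pe)
    return KappaResult(po=po, pe=pe, kappa=kappa, pabak=pab, band=altman_band(kappa))


def pabak_adjusted_table(table: ContingencyTable2x2) -> Tuple[float, float, float, float]:
    """The prevalence/bias-adjusted table ((a+d)/2, (b+c)/2, (b+c)/2, (a+d)/2)."""
    m = (table.a + table.d) / 2
    s = (table.b + table.c) / 2
    return (m, s, s, m)


def pabak(table: ContingencyTable2x2) -> float:
    """Prevalence- and bias-adjusted kappa: 2*p_o - 1.

    Identically equals Cohen's kappa computed on the adjusted table with
    both margins balanced.
    """
    return 2 * (table.a + table.d) / table.n - 1


# ---------------------------------------------------------------------------
# Verbal bands


@dataclass(frozen=True)
class BandTable:
    """Ordered contiguous bands partitioning a range, with a boundary convention.

    With ``upper_inclusive=True`` a boundary value belongs to the band below
    it (bands read (lo, hi]); otherwise to the band above ([lo, hi)).  The
    first/last band always includes the range endpoint.
    """

    bounds: Tuple[Tuple[float, float, str], ...]
    upper_inclusive: bool = True

    def lookup(self, value: float) -> str:
        lo0 = self.bounds[0][0]
        hi_last = self.bounds[-1][1]
        if not (lo0 <= value <= hi_last):
            raise ValueError(f"value {value} outside band range [{lo0}, {hi_last}]")
        for lo, hi, label in self.bounds[:-1]:
            if value <= hi if self.upper_inclusive else value < hi:
                return label
        return self.bounds[-1][2]


#: Altman's verbal interpretation of kappa (upper-inclusive boundaries, so
#: that 0.60 reads "moderate" and 0.61 reads "good").
ALTMAN_BANDS = BandTable(
    bounds=(
        (-1.00, 0.20, "poor"),
        (0.20, 0.40, "fair"),
        (0.40, 0.60, "moderate"),
        (0.60, 0.80, "good"),
        (0.80, 1.00, "very good"),
    ),
    upper_inclusive=True,
)

#: Guilford's verbal interpretation of a correlation magnitude |r|
#: (lower-inclusive: 0.9 already reads "very high").
GUILFORD_BANDS = BandTable(
    bounds=(
        (0.0, 0.2, "negligible"),
        (0.2, 0.4, "low"),
        (0.4, 0.7, "moderate"),
        (0.7, 0.9, "high"),
        (0.9, 1.0, "very high"),
    ),
    upper_inclusive=False,
)

BAND_REGISTRY: Dict[str, BandTable] = {"altman": ALTMAN_BANDS, "guilford": GUILFORD_BANDS}


def altman_band(kappa: float) -> str:
    """Altman's verbal band for a kappa value in [-1, 1]."""
    return ALTMAN_BANDS.lookup(kappa)


def guilford_band(r: float, bands: BandTable | None = None) -> str:
    """Guilford's verbal band for a correlation, looked up on the magnitude |r|
    so that negative correlations (e.g. score vs FEV1) band by strength."""
    if abs(r) > 1:
        raise ValueError(f"|r| must be <= 1, got {r}")
    return (bands or GUILFORD_BANDS).lookup(abs(r))


# ---------------------------------------------------------------------------
# Continuous agreement


@dataclass(frozen=True)
class CCCResult:
    """Lin's concordance correlation coefficient with its Fisher-z CI."""

    rho_c: float
    ci_low: float
    ci_high: float
    pearson_r: float
    n: int
    degenerate: bool = False


def lins_ccc(x: Sequence[float], y: Sequence[float], alpha: float = 0.05) -> CCCResult:
    """Lin's concordance correlation coefficient for paired measurements.

    rho_c = 2*s_xy / (s_x^2 + s_y^2 + (mean x - mean y)^2) with biased (1/n)
    moment estimators; the confidence interval applies the Fisher
    z-transform with Lin's asymptotic variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("need at least 3 pairs")
    sx2 = np.var(x)
    sy2 = np.var(y)
    if sx2 == 0 and sy2 == 0:
        return CCCResult(
            rho_c=math.nan, ci_low=math.nan, ci_high=math.nan,
            pearson_r=math.nan, n=n, degenerate=True,
        )
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    dmean = x.mean() - y.mean()
    rho_c = 2 * sxy / (sx2 + sy2 + dmean**2)

    if sx2 == 0 or sy2 == 0:
        r = math.nan
        lo = hi = math.nan
    else:
        r = sxy / math.sqrt(sx2 * sy2)
        lo, hi = _ccc_fisher_ci(rho_c, r, dmean, sx2, sy2, n, alpha)
    return CCCResult(rho_c=float(rho_c), ci_low=lo, ci_high=hi, pearson_r=float(r), n=n)


def _ccc_fisher_ci(rho_c, r, dmean, sx2, sy2, n, alpha):
    # Lin (1989) asymptotic variance of z = atanh(rho_c).
    if abs(rho_c) >= 1 or r == 0:
        return float(rho_c), float(rho_c)
    u2 = dmean**2 / math.sqrt(sx2 * sy2)
    one_m = 1 - rho_c**2
    var_z = (
        (1 - r**2) * rho_c**2 / (one_m * r**2)
        + 2 * rho_c**3 * (1 - rho_c) * u2 / (r * one_m**2)
        - rho_c**4 * u2**2 / (2 * r**2 * one_m**2)
    ) / (n - 2)
    var_z = max(var_z, 0.0)
    z = math.atanh(rho_c)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    half = zcrit * math.sqrt(var_z)
    return math.tanh(z - half), math.tanh(z + half)


@dataclass(frozen=True)
class SlopeCIResult:
    """Least-squares slope with its t-based confidence interval."""

    slope: float
    ci_low: float
    ci_high: float
    intercept: float


def regression_slope_ci(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> SlopeCIResult:
    """OLS slope and intercept of y on x, with slope CI = b +/- t_{1-a/2,n-2}*SE(b)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n or n < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: slope undefined")
    sxx = np.sum((x - x.mean()) ** 2)
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    s2 = float(np.sum(resid**2) / (n - 2))
    se = math.sqrt(s2 / sxx)
    tcrit = stats.t.ppf(1 - alpha / 2, n - 2)
    return SlopeCIResult(
        slope=slope, ci_low=slope - tcrit * se, ci_high=slope + tcrit * se,
        intercept=intercept,
    )


# ---------------------------------------------------------------------------
# Per-sign summary (the shape of the interobserver table)


@dataclass(frozen=True)
class SignAgreementRow:
    """Min/max/mean agreement for one sign across lung fields (or cavities)."""

    sign: str
    kappa_min: Optional[float]
    kappa_max: Optional[float]
    kappa_mean: Optional[float]
    band: Optional[str]
    n_units: int
    n_degenerate: int


def per_sign_agreement_summary(
    ratings: Dict[str, Tuple[np.ndarray, np.ndarray]],
    statistic: str = "pabak",
) -> List[SignAgreementRow]:
    """Summarize two raters' binary assessments per sign.

    Parameters
    ----------
    ratings
        Maps sign name to a pair of (n_patients x n_units) binary matrices,
        one per rater.  Units are lung fields for most signs; pleural fluid
        is assessed per pleural cavity, so its matrices have 2 columns.
    statistic
        ``"pabak"`` (prevalence/bias-corrected, default) or ``"kappa"``
        (raw Cohen's kappa, skipping degenerate fields).

    Returns one row per sign with the min, max and mean of the per-unit
    statistic and the Altman band of the mean.  A sign whose every unit is
    degenerate under raw kappa is reported with an undefined summary.
    """
    if statistic not in ("pabak", "kappa"):
        raise ValueError("statistic must be 'pabak' or 'kappa'")
    rows: List[SignAgreementRow] = []
    for sign, (r1, r2) in ratings.items():
        r1 = np.asarray(r1)
        r2 = np.asarray(r2)
        if r1.shape != r2.shape or r1.ndim != 2:
            raise ValueError(f"{sign}: raters must be equal-shape 2-D matrices")
        values: List[float] = []
        n_degen = 0
        for j in range(r1.shape[1]):
            table = contingency_from_ratings(r1[:, j], r2[:, j])
            if statistic == "pabak":
                values.append(pabak(table))
            else:
                res = cohens_kappa(table)
                if res.degenerate:
                    n_degen += 1
                else:
                    values.append(res.kappa)
        if not values:
            rows.append(SignAgreementRow(sign, None, None, None, None, r1.shape[1], n_degen))
            continue
        mean = float(np.mean(values))
        rows.append(
            SignAgreementRow(
                sign=sign,
                kappa_min=float(min(values)),
                kappa_max=float(max(values)),
                kappa_mean=mean,
                band=altman_band(mean),
                n_units=r1.shape[1],
                n_degenerate=n_degen,
            )
        )
    return rows


def band_census(rows: Sequence[SignAgreementRow]) -> Dict[str, int]:
    """Count the signs per Altman band of the mean statistic."""
    census: Dict[str, int] = {}
    for row in rows:
        label = row.band if row.band is not None else "undefined"
        census[label] = census.get(label, 0) + 1
    return census
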