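# Methods

## The scoring model

The score engine consumes structured per-field findings, never images.
Twelve lung fields (codes `aUL … pLR`) partition into four scoring areas —
side (right/left) × surface (anterior/posterior) — of three fields each.
Per area, five categories are graded 0/1/2 and summed; small-consolidation
and Am-line counts are summed across the area's three fields before
grading, major-consolidation sizes are pooled, and the pleural-line and
B-line rules look at the three fields individually. The per-area subtotal
is bounded by 11 (5 × 2 + bonus) and the total by 44.

Interpretation choices that the published rule table leaves open, and how
this package resolves them:

- **B-line bonus.** The footnote rule "+1 when 1–3 B-lines are present in
  all 3 fields" is ambiguous: read strictly (every field count in [1, 3])
  the bonus can never coexist with a nonzero base grade, so the printed
  maximum of 44 would be unattainable. The default (`BonusRule.
  any_b_in_all_fields`) awards the bonus when every field shows at least
  one B-line — a field with ≥4 also contains 1–3 of them — which makes 44
  attainable. The strict reading and a disabled-bonus variant remain
  available, and `max_total()` enumerates the attainable maximum under
  each (44 / 40 / 40) rather than assuming it.
- **"Widespread" pleural abnormality** is graded 2 when at least two of
  the area's three fields are at least "present"; a single "present" field
  grades 1. This is the weakest reading that still separates "widespread"
  from single-field disease.
- **Boundary values** are inclusive as printed: 40 mm is still a "single
  ≤40 mm" major consolidation; an area total of exactly 3 small
  consolidations grades 1; two Am-lines grade 1.
- **Pleural-line morphology** (irregularity, fragmentation, blurring,
  ragging, thickening) is collapsed into one ordinal severity
  (absent/minimal/present/marked) because that is what the rule table
  consumes; morphologies can be kept as free-text tags.
- **Pleural fluid** (per hemithorax, mm) is reported descriptively and
  deliberately excluded from the score.

The modified Chrispin–Norman radiographic score is config-driven: any item
set whose grades are 0/1/2 is summed. The default — three
chest-configuration items plus four zones × four shadow types (bronchial
line, mottled, ring, large soft), maximum 38 — is this package's own
documented assumption; published itemizations vary and the score here is
used only as a correlated severity covariate. Bronchial-line and ring
shadows form a "consistent with bronchiectasis" subscore.

## Agreement statistics

For paired binary field readings, Cohen's κ uses the standard 2×2 formulas
with p_e from the margins; a table where both raters are constant has
p_e = 1 and is returned flagged as degenerate rather than as NaN. PABAK,
the prevalence- and bias-adjusted κ, is 2·p_o − 1 and identically equals κ
on the margin-balanced adjusted table ((a+d)/2, (b+c)/2, (b+c)/2, (a+d)/2);
a property test asserts the identity to machine precision. Because the
source analyses do not say whether their per-field values are raw or
adjusted κ, the per-sign summary computes either (PABAK by default, raw κ
on request, degenerate fields skipped and counted).

Verbal bands: Altman's κ bands are upper-inclusive
(≤0.20 poor, (0.20,0.40] fair, (0.40,0.60] moderate, (0.60,0.80] good,
(0.80,1.00] very good) — the convention is pinned by the only decidable
published case, a mean of 0.60 reading "moderate" while 0.61 reads "good".
Guilford's correlation bands apply to |r| (so a strong negative
score–FEV1 correlation is "high") and are lower-inclusive
(<0.2 negligible, 0.2–0.4 low, 0.4–0.7 moderate, 0.7–0.9 high,
≥0.9 very high). Published usage is not fully consistent with any one
Guilford table (0.87 is sometimes labelled "very high"); the band table is
therefore configurable and the default is the common textbook one.

Lin's concordance coefficient uses biased (1/n) moment estimators,
ρ_c = 2·s_xy/(s_x² + s_y² + (x̄−ȳ)²), with the Fisher-z confidence
interval from Lin's asymptotic variance. |ρ_c| ≤ |r| always, with equality
iff the two means and variances coincide. The regression-slope interval is
b ± t(1−α/2, n−2)·SE(b).

## Cohort analytics

Prevalence is patient-level ("sign in at least one lung field"; any
pleural-line abnormality including "minimal" counts for prevalence even
though "minimal" grades 0). Percentages are rounded to the nearest integer
(halves up), which reproduces every published prevalence from its count
and group size. The 95% CI is the Wilson score interval; the plain
interval is the default because its coverage is close to nominal at cohort
sizes in the hundreds (exact coverage 0.944 at n=131, p=0.3), while the
continuity-corrected variant (available via ``continuity=True``) is
conservative (0.965 at the same point, and its empirical coverage
estimates routinely exceed 0.97). Both variants are verified against R's
`prop.test` to 1e-9.

Two-group comparisons default to a policy the source description leaves
garbled: Shapiro–Wilk per group at α = 0.05, Student's t when both groups
pass, Mann–Whitney–Wilcoxon otherwise; either test can be forced.
Kruskal–Wallis (tie-corrected) handles ≥3 groups. Fisher's exact test uses
the minimum-likelihood two-sided convention (scipy's default) with the
doubling convention available; the odds ratio is the conditional MLE, with
infinite values flagged rather than clipped. No multiple-testing
correction is applied anywhere — reports carry raw p-values, matching how
such single-cohort scoring studies are analysed.

## The synthetic cohort

No per-patient data are deposited for this kind of study, so the
generator emulates the statistical structure the analyses assume. It is a
stand-in calibrated to published marginals and correlation magnitudes,
never a model of the real data-generating process.

- **Ages**: min + range·Beta(1.5, 2.2) on (0.1, 18) years, putting the
  median near 7 — the study-like age profile.
- **Latent severity**: z_sev = w·z_age + √(1−w²)·ε with w = 0.85, where
  z_age is the normal-scores transform of age. The scale is arbitrary;
  only rank correlations matter downstream.
- **Sign presence**: each sign draws a Gaussian-copula uniform correlated
  with z_sev (loadings 0.35–0.85, strongest for advanced-disease signs)
  and exactly round(p·n) patients — those with the highest draws — carry
  the sign. Rank-thresholding makes every configured patient-level
  prevalence exact up to integer rounding while preserving the severity
  link; a Bernoulli sampler would add ~0.7 pp of noise per sign at
  n = 5000. "Single B-lines" (≥1 B-line) logically nests the numerous-
  and confluent-B patients, so its marginal is hit by topping up
  non-nested patients; a configuration asking for fewer single-B than
  numerous-B patients is unsatisfiable for any generator.
- **Field placement**: affected-field counts grow with severity; fields
  are drawn without replacement with apico-basal row weights
  (lower 4 : middle 2 : upper 1), anterior dominance (×2) for small
  consolidations, and a stronger basal tilt for numerous B-lines.
  Controls show single B-lines only in middle/lower fields.
- **Counts and sizes**: 1 + Poisson for per-field B-line (capped at 3 for
  single-B fields), Am-line and small-consolidation counts; major sizes
  11 + Gamma(2, 9) mm capped at 80; ≥4 + Poisson B-lines in numerous
  fields. Pleural-line severity draws "marked" with probability increasing
  in severity. Pleural fluid is basal, 1–7 mm (≤2 mm in controls).
- **Covariates** (CF group): a radiograph whose item grades fill a
  severity-tracking point target; FEV1/FVC %pred decreasing and LCI
  increasing in severity with Gaussian noise; pathogen status (marginal
  48%) and fungal infection (9%) as severity-correlated thresholds, with
  the pathogen subtype ordered chronic > intermittent ≈ previously
  reported > first-time. Missingness matches the study-like subsets
  (radiograph ~63%, spirometry ~59%, washout ~49% present). With these
  defaults the realised structure is score–age r ≈ 0.74, radiographic
  score r ≈ 0.82, FEV1 r ≈ −0.77, LCI r ≈ 0.74 — the intended
  "high/very-high magnitude, correct sign" regime.
- **Second observer**: binary per-field presences flip independently and
  symmetrically at per-sign rates ε, so E[p_o] = 1 − ε and
  PABAK = 1 − 2ε exactly; `calibrate_flip_rate` inverts this. Default
  rates land the per-sign agreement at study-like levels (very good for
  most signs, weakest for Z-lines). The record-level second observer adds
  ±1 count jitter that never crosses the numerous-B threshold, keeping
  binary agreement governed by the flip rates while the score totals
  disagree realistically (CCC ≈ 0.99 at the defaults).

Everything is driven by explicit `numpy` Generator seeds; identical
configs give byte-identical cohorts.

What passing tests on synthetic data do *not* show: the generator cannot
validate the score against real disease (no image interpretation, no true
severity), and its joint distribution is one convenient choice among many
consistent with the published marginals. Tests against it demonstrate that
the pipeline recovers whatever structure the data carry — calibration
recovery — not that the score is clinically valid.

## Numerical choices and problem sizes

- Oracle-equivalence sweeps use 1000 random records (exact integer
  comparison); algebraic identities (PABAK, CCC brute-force moments,
  OLS-vs-matrix) are asserted at 1e-10 to 1e-12.
- Calibration-recovery checks use n = 5000 cohorts (±2 pp prevalence,
  ±0.03 PABAK) and n = 500 for correlation recovery (±0.1), sizes at
  which the checks are stable and the whole suite runs in seconds.
- Wilson-coverage checks use 2000 binomial replicates at n = 131,
  p = 0.3.
- Degenerate inputs (constant raters, constant regressors, empty
  consolidation lists, all-absent records) return flagged results or raise
  typed errors; NaN never propagates silently.

## Known limitations

- The synthetic cohort is cross-sectional only; no longitudinal change,
  exacerbations or treatment effects.
- The Chrispin–Norman itemization is an assumption; totals are comparable
  within this package, not across published variants.
- Agreement tooling covers exactly two raters; no Fleiss/Krippendorff
  generalisation.
- The CLI and CSV formats handle one unambiguous dialect (comma, UTF-8,
  `.` decimal) by design.
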