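"""Generate a study-like synthetic cohort and run the cohort analysis.

Draws 131 CF patients and 32 healthy controls with the default calibrated
prevalences, prints the per-sign prevalence table (count, rounded percent,
Wilson 95% CI) and the severity-score correlations with age, the
radiographic score and lung function.
"""

from cflus import (
    GeneratorConfig,
    generate_cohort,
    prevalence_table,
    score_vs_covariates_report,
)

cf = generate_cohort(GeneratorConfig(n_patients=131, group="cf", seed=42))
hc = generate_cohort(GeneratorConfig(n_patients=32, group="control", seed=43))

print(f"{'sign':28s} {'CF n(%)':>12s} {'control n(%)':>14s}")
rows = prevalence_table(cf + hc)
by_sign = {}
for r in rows:
    by_sign.setdefault(r.sign, {})[r.group] = r
for sign, groups in by_sign.items():
    c, h = groups["cf"], groups["control"]
    print(f"{sign:28s} {c.n_with:4d} ({c.pct:3d}%) {h.n_with:6d} ({h.pct:3d}%)")

rep = score_vs_covariates_report(cf)
print("\nseverity-score correlations (CF group):")
for name, res in rep.correlations.items():
    print(
        f"  {name:16s} r = {res.r:+.2f} ({res.guilford_label}), "
        f"R^2 = {res.r_squared:.2f}, n = {res.n}"
    )
for name, cmp in rep.comparisons.items():
    means = " vs ".join(f"{g}={m:.2f}" for g, m in zip(cmp.groups, cmp.means))
    print(f"  {name:16s} means {means} ({cmp.test_used}, p = {cmp.p_value:.2g})")
print(
    "\nA positive age correlation and the higher scores in infected patients\n"
    "reproduce the structure the generator is calibrated to; controls show\n"
    "none of the CF-specific signs."
)
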