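# cflus

Semi-quantitative lung-ultrasound (LUS) severity scoring for children with
cystic fibrosis (CF), with the statistics needed to validate such a score:
interobserver agreement, radiographic cross-validation and cohort-level
analysis. Written for clinical researchers who grade sonographic findings
per lung field and want a reproducible, tested path from finding records to
severity scores, agreement tables and correlation reports — plus a
calibrated synthetic-cohort generator, because per-patient data from
scoring studies are rarely deposited.

## The score

The chest is divided into 12 lung fields (anterior/posterior × upper/
middle/lower × left/right) grouped into 4 areas of 3 fields. Each area
grades five finding categories on a 0/1/2 intensity scale:

| category | 0 | 1 | 2 |
|---|---|---|---|
| small consolidations (≤10 mm, area total) | ≤1 | 2–3 | ≥4 |
| major consolidations (>10 mm, pooled) | absent | single ≤40 mm | ≥2, or 1 >40 mm |
| pleural-line abnormality | absent/minimal | present, not marked | marked or widespread |
| Am-lines (area total) | 0 | ≤2 | ≥3 |
| B-lines (per field, per scan) | ≤3 | confluent, or ≥4 in 1 of 3 fields | ≥4 in ≥2 of 3 fields |

One bonus point per area is added when B-lines appear in all three of its
fields, so the total spans 0–44. `max_total()` verifies the maximum by
enumeration under each supported reading of the bonus rule. Pleural fluid
is recorded per hemithorax and reported, never scored.

Agreement statistics: Cohen's κ = (p_o − p_e)/(1 − p_e) on 2×2 tables of
paired binary field readings, its prevalence- and bias-adjusted form
PABAK = 2·p_o − 1, Altman's verbal bands, Lin's concordance
ρ_c = 2·s_xy/(s_x² + s_y² + (x̄ − ȳ)²) with a Fisher-z CI, and the OLS
slope with its t-based CI. Cohort analytics: prevalence tables with Wilson
95% CIs, Pearson r with the least-squares line and R², Mann–Whitney /
Student-t / Kruskal–Wallis comparisons, Fisher's exact test.

## Worked example

```sh
python examples/score_a_patient.py
```

```
patient demo-001, age 11.5 y
area   small major pleural am b-lines bonus subtotal
RL-A       1     0       1  0       1     0        3
RL-P       0     1       2  0       0     0        3
LL-A       0     0       0  0       0     0        0
LL-P       0     0       0  1       0     0        1
total: 7 / 44
```

The right anterior area scores 3: two small consolidations (grade 1), a
"present" pleural line in one field (grade 1) and one field with ≥4
B-lines (grade 1). The right posterior area adds a single 30-mm
consolidation (grade 1) and a marked pleural line (grade 2); two Am-lines
at the left posterior base contribute 1. A total of 7/44 indicates mild
structural disease.

`examples/simulate_and_analyse.py` draws a 131-patient synthetic CF cohort
plus 32 controls and prints the prevalence table and severity-score
correlations (score–age r ≈ +0.74, radiographic score r ≈ +0.82,
FEV1 %pred r ≈ −0.77, LCI r ≈ +0.80, higher scores under CF-pathogen and
fungal infection); `examples/interobserver_agreement.py` simulates a
38-patient second-observer reading and prints the per-sign κ table and the
score-level concordance (CCC ≈ 0.99, slope CI around 1).

There is also a thin CLI:

```sh
cflus simulate --n 131 --seed 7 --second-observer --out cohort/
cflus score cohort/ --out scores.csv
cflus agree cohort/ratings.csv --out agreement.csv
cflus report cohort/ --out report/
```

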