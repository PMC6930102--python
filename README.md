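# frailtykit

Deficit-accumulation frailty indices from patient-reported outcomes, with
the validation analytics needed to compare a retrospectively generated
index against a prospectively specified one.

## The problem

Clinical trials in older adults increasingly need a frailty measure, but a
dedicated prospective frailty battery (disability, cognition, physical
phenotype, depression, multimorbidity) is expensive to administer. The
deficit-accumulation approach (Mitnitski & Rockwood) offers an
alternative: count health deficits — symptoms, functional limitations,
diseases — each scored 0 (absent), 0.5 (partial) or 1 (present), and form

    FI = deficit score / n

where *n* is the number of non-missing components. Subjects are
categorised as **non-frail** (FI ≤ 0.08), **pre-frail** (0.08 < FI ≤ 0.25)
or **frail** (FI > 0.25). Because many trials already collect the SF-36
and EQ-5D-3L questionnaires plus a medical history, a frailty index can be
generated retrospectively from routinely collected data — if it behaves
like a proper FI: it rises with age, no component saturates at younger
ages, and it concords with a prospectively specified index.

`frailtykit` implements:

* **RAND-style SF-36 scoring** into the eight 0–100 scales, and
  **EQ-5D-3L utilities** under pluggable value sets (tariffs);
* the fully specified **retrospective 43-item FI** (14 comorbidities +
  25 SF-36 deficits + 4 EQ-5D deficits) and a schema-driven engine for
  **36-item prospective batteries**, with missing-aware normalisation and
  a configurable completeness floor;
* **validation analytics**: 3×3 category cross-tabulation, percent
  agreement and Kendall's τ-b from the table marginals, linear and
  exponential FI-versus-age fits, per-item saturation diagnostics, and
  post-vaccination PF/utility trajectory summaries flagged against
  minimal clinically important differences (3.3 PF points, 0.074 utility);
* an **age-structured synthetic cohort generator** (shared latent
  liability on the log-odds scale) so every analysis is testable without
  any deposited subject-level data.

## Worked example

```python
import numpy as np
import frailtykit as fk

# A published 3x3 frailty cross-tabulation (retrospective rows,
# prospective columns, categories ordered non-frail < pre-frail < frail)
ct = fk.CrossTab3x3(np.array([[178, 57, 1],
                              [14, 108, 21],
                              [0,   4,  18]]))
count, frac = fk.agreement(ct)
tau = fk.kendall_tau_b(ct)
print(count, round(100 * frac, 1), round(tau.tau, 4), tau.p_value < 0.001)
# 304 75.8 0.6831 True
```

304 of the 401 paired subjects (75.8 %) fall in the same category under
both indices, and τ-b = 0.68 (p < .001) indicates strong ordinal
concordance. Evaluating a linear age trend:

```python
ages = np.arange(50, 86, dtype=float)
fit = fk.fit_age_trend(ages, -0.1618 + 0.0040 * ages)
print(round(fit.predict(90)[0], 4))
# 0.1982
```

an FI intercept of −0.1618 and slope of 0.0040 per year put the mean FI
at about 0.2 by age 90 — most 90-year-olds are pre-frail or frail.

A full pipeline on a synthetic cohort (simulate → score → both FIs →
concordance, trends, saturation, trajectories):

```bash
frailtykit run-all --outdir out --seed 1
# pipeline complete: 401 subjects, outputs in out
```

writes per-schema FI tables, `concordance.json`, `trend_fits.csv`,
`saturation_*.csv`, `trajectories.csv` and a run manifest.

## Layout

| Module | Contents |
| --- | --- |
| `frailtykit.sf36` | SF-36 item recodes, eight-scale scoring, half-scale rule |
| `frailtykit.eq5d` | EQ-5D-3L levels, value-set loading, utility lookup |
| `frailtykit.deficits` | deficit schemas, FI computation, categorisation, saturation |
| `frailtykit.analytics` | cross-tabs, agreement, τ-b, age trends, trajectories |
| `frailtykit.synthetic` | latent-liability cohort and trajectory simulation |
| `frailtykit.io` | CSV ingestion, run configuration, pipeline orchestration |
| `frailtykit.cli` | `frailtykit` command with simulate/score/concordance/trend/trajectories/run-all |

See `docs/methods.md` for the statistical details and the assumptions
behind the packaged defaults.
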