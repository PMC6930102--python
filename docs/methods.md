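# Methods

## The deficit-accumulation frailty index

A frailty index (FI) is the proportion of health deficits present out of
those assessed. Each deficit item maps a questionnaire response to a
score in {0, 0.5, 1} with a maximum contribution of 1; half-scores arise
only from middle response categories, never by interpolation. For a
subject with deficit sum *s* over *n* non-missing items, FI = *s*/*n*.
Categories use the conventional cutoffs: non-frail (FI ≤ 0.08), pre-frail
(0.08 < FI ≤ 0.25), frail (FI > 0.25); the boundary value belongs to the
lower category at both cutoffs.

**Completeness floor.** An FI computed from too few answered items is
unreliable. The default requires n/N ≥ 0.8 (common FI practice);
below it the FI is reported missing. The floor is configurable.

**Retrospective 43-item schema.** Built in code
(`build_retrospective_schema`): 14 medical-history comorbidities (1 point
each when present), 25 SF-36 deficits — the general-health rating (q1),
the four health-belief statements (q11a–d, with the positively worded
pair reverse-keyed), the ten physical-functioning limitations (q3a–j,
"limited a lot" = 1, "limited a little" = 0.5), the nine vitality/mental-
health frequency items (q9a–i, with the four positive-affect items keyed
so that *never* feeling well is the deficit), and the health-change item
(q2) — plus 4 EQ-5D-3L deficits (mobility, anxiety/depression, self-care,
usual activities; worst level = 1, middle = 0.5). Pain/discomfort is not
a deficit component (it feeds only the utility). The maxima decompose as
14 + 25 + 4 = 43.

Only one of the 14 comorbidity names (high blood pressure) is fixed by
the source material; the other condition names packaged here are a
documented assumption and the list is configurable. A *missing*
comorbidity (not asked) is distinguished from *absent*: missing drops out
of the denominator, absent scores 0.

**Prospective 36-item schema.** The battery's domain structure is fixed
(disability ×14, cognition ×1, self-rated health and health change ×2,
physical status ×4, depression/exhaustion ×1, multimorbidity ×14) but its
instrument-level operationalisations are study-specific, so the engine is
schema-driven: any YAML/JSON config declaring 36 items with complete
{0, 0.5, 1} mappings is accepted, and violations are rejected naming the
item. The packaged default (`data/prospective_fi.yaml`) encodes
one-point-per-deficit mappings with assumed cut-points; its header flags
every assumption.

**Saturation.** A candidate deficit that is already highly prevalent in
the youngest stratum cannot discriminate frailty. The diagnostic reports
per-item prevalence of score > 0 overall and within ages 50–59, flagging
items whose youngest-stratum prevalence reaches the threshold (default
0.8 — the concept is standard, the number is this package's choice). An
empty youngest stratum yields an explicit not-evaluable status.

## Questionnaire scoring

**SF-36.** Public-domain RAND-36 convention: each item is recoded to
0–100 (higher = better, with standard reversals), and a scale is the mean
of its answered items. A scale is missing when more than half its items
are missing; otherwise averaging the answered items is equivalent to
person-mean imputation. The q9 battery uses the five-level response set
(All/Most/Some/A little/None of the time) with equally spaced recodes
0/25/50/75/100; no norm-based scoring. Labels are matched
case-insensitively after whitespace and apostrophe normalisation, and
numeric codings are accepted via a declared code map.

**EQ-5D-3L.** A complete five-dimension profile is converted to a utility
by exact lookup in a 243-state table expanded from a value-set JSON
(either explicit states or an additive decrement model: constant on any
departure from full health, per-dimension level decrements, an extra term
when any dimension is at level 3). Utility is undefined if any dimension
is missing. The packaged default is the UK time-trade-off tariff (MVH
study, Dolan 1997) — chosen because its coefficients are verifiable
against well-known anchor states (21111 = 0.850, 33333 = −0.594); any
other published tariff plugs in as data. The full-health anchor must be
exactly 1.0 and is validated on load.

## Concordance

Two categorisations are compared on a 3×3 ordinal cross-tabulation.
Percent agreement is trace/total. Kendall's τ-b is computed from the
table:

    τ-b = (C − D) / √((n₀ − n₁)(n₀ − n₂))

with C/D the concordant/discordant pair counts, n₀ = n(n−1)/2, and n₁, n₂
the tied-pair counts from the row and column marginals. The default
p-value uses the standard tie-corrected normal approximation of the null
distribution of C − D (identical to the large-sample test in
`scipy.stats.kendalltau`, against which the statistic is cross-checked in
the tests; an exhaustive O(n²) pair-enumeration oracle provides the
independent check of the statistic itself). A Monte Carlo permutation
p-value is available for grand totals ≤ 200. A degenerate table (all mass
in one row or column) reports τ-b as undefined rather than 0.

## Age trends

`fit_age_trend` performs OLS of FI on age (linear) or of log FI on age
(exponential), the latter excluding FI = 0 records with a reported count —
the pragmatic reading of an "exponential" FI-age relationship. Fitting
granularity defaults to subject-level points (statistically preferable);
a mean-FI-per-integer-age option mirrors the aggregated scatter often
plotted. Predictions outside the fitted age range carry an extrapolation
flag. Fits require ≥ 3 distinct ages.

## Post-dose trajectories

Daily PF and utility records (days 0–7) are summarised per frailty
category: daily means, change from the category's Day-0 mean, and a flag
for whether |change| reaches the minimal clinically important difference
— 3.3 points for SF-36 PF, 0.074 for EQ-5D utility. The flag is inclusive
at the threshold (implemented with a 1e−9 tolerance so an exact-threshold
change is never lost to float rounding); direction is available from the
signed change. Categories with no subjects are omitted with a logged
notice; a category without Day 0 is an error.

## Synthetic cohorts

No subject-level data is deposited for the study design this package
targets, so the generator is first-class, tested code. Each subject in
three age strata (50–59, 60–69, ≥70; default sizes 134/133/134, ~401
total) receives a latent liability on the log-odds scale

    η_i = logit(p₀) + γ·(age_i − 50) + u_i,   u_i ~ N(0, τ²),

and every item response is drawn with deficit probability expit(η_i).
Given a deficit it is *full* (worst category) with probability
`severe_frac`, else *partial* (the 0.5 category where the item has one).
Zero-deficit responses are drawn uniformly among the item's zero-scoring
labels. Defaults: p₀ = 0.10, γ = 0.045 per year, τ = 1.0,
`severe_frac` = 0.25 — chosen so deficit prevalence, the FI-age gradient
(a few thousandths of FI per year) and the category mix look like a
community-dwelling 50+ trial population. The shared u_i induces the
inter-item correlation that makes the two indices concord; the
prospective battery is generated from the same liability so both indices
are computable on one synthetic subject.

The model-implied mean FI at an age is E_u[expit(η)]·mean_j c_j with
c_j = 0.5 + 0.5·severe_frac for graded items and 1 for binary ones,
evaluated by Gauss–Hermite quadrature; `implied_linear_slope` projects it
onto age under the generator's age distribution, giving the value a
subject-level OLS slope converges to. Tests and the acceptance script
check the fitted slope against this generative value within 3 standard
errors on 5,000-subject cohorts (sized to keep the whole suite fast while
leaving sampling error well below the effects of interest).

Post-dose trajectories take each subject's scored PF and utility as the
Day-0 baseline and add a per-category reactogenicity dip (default: a pure
Day-1 dip of −2.1 PF / −0.045 utility in the non-frail, −3.0 / −0.035 in
the frail, recovered by Day 2) plus independent Gaussian noise — the
transient-dip-and-recovery shape such trials report.

**What the generator does not emulate:** real marginal prevalences of
individual deficits (all items are exchangeable given the liability),
item-specific difficulty, differential missingness, within-subject visit
correlation beyond the static liability, and any treatment effect.
Passing tests therefore demonstrate the *pipeline's* correctness and the
qualitative age/concordance structure, not calibration to any particular
trial population.

## Numerical and design notes

* Tie-polynomial sums in the τ-b variance use Python integers to avoid
  int64 overflow on large tables.
* τ-b from the table formula equals exhaustive pair enumeration exactly
  (asserted to 1e−12 on randomized tables).
* CSV is the canonical interchange (UTF-8, "." decimal, missing = empty
  field); written FI tables round-trip losslessly at full precision.
* Pipeline runs are deterministic given config and seed; the manifest
  records config, version and counts (its timestamp is the only
  non-deterministic output field).
* The CLI is a thin layer over the library; every subcommand's work is a
  documented library call.

## Known limitations

* The packaged prospective schema cannot claim fidelity to any specific
  trial's battery; it is a structurally faithful, explicitly assumed
  default.
* Norm-based SF-36 scoring, SF-12, EQ-5D-5L and crosswalks are out of
  scope, as are weighted-kappa agreement and mixed-model longitudinal
  analyses.
* Continuous-score deficits (e.g. mapping a raw 0–30 cognitive score to a
  graded deficit) are not supported; deficits are {0, 0.5, 1} only.
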