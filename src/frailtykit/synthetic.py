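"""Age-structured synthetic cohorts of questionnaire records.

No subject-level data is deposited for the trial this package models, so
every analysis here must be exercisable on simulated cohorts.  The
generator draws subjects in three age strata (50-59 / 60-69 / >=70) and
gives each a latent frailty liability on the log-odds scale:

    eta_i = logit(p0) + gamma * (age_i - 50) + u_i,   u_i ~ N(0, tau^2)

Each item response is then drawn with deficit probability expit(eta_i):
the shared subject term u_i induces the inter-item (and inter-index)
correlation that makes the two frailty indices concord, while the age
gradient gamma makes deficit prevalence — hence the frailty index — rise
with age.  Given a deficit, it is a full deficit (worst response
category) with probability ``severe_frac`` and a partial one (the 0.5
category, where the item has one) otherwise.  Responses are emitted in
the exact label dialect the scoring modules consume.

The model's implied mean FI per age is available in closed form up to a
one-dimensional integral over u (Gauss-Hermite quadrature), so fitted
age slopes can be checked against the generative value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.special import expit, logit

from .deficits import (
    DEFAULT_COMORBIDITIES,
    DeficitItem,
    DeficitSchema,
    build_prospective_schema,
    build_retrospective_schema,
)

__all__ = [
    "AGE_STRATA",
    "CohortSpec",
    "simulate_cohort",
    "simulate_postdose_trajectories",
    "expected_fi",
    "implied_linear_slope",
]

AGE_STRATA: tuple[tuple[int, int], ...] = ((50, 59), (60, 69), (70, 85))
_STRATUM_LABELS = ("50-59", "60-69", ">=70")


class CohortSpec(BaseModel):
    """Parameters of the synthetic cohort generator.

    Defaults mirror the study conditions: ~401 subjects split evenly
    across the three age strata, deficit prevalence rising with age so
    the mean FI increases on the order of a few thousandths per year.
    """

    n_per_stratum: tuple[int, int, int] = (134, 133, 134)
    baseline_prob: float = Field(0.10, ge=0.0, le=1.0,
                                 description="per-item deficit probability at age 50, median liability")
    age_gradient: float = Field(0.045, description="log-odds of deficit per year of age")
    liability_sd: float = Field(1.0, ge=0.0,
                                description="SD of the shared subject liability (inter-item correlation knob)")
    severe_frac: float = Field(0.25, ge=0.0, le=1.0,
                               description="P(full deficit | any deficit)")
    missing_rate: float = Field(0.0, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_sizes(self) -> "CohortSpec":
        if any(n < 0 for n in self.n_per_stratum):
            raise ValueError("stratum sizes must be non-negative")
        return self


# Emission labels for grades (good choices, partial, worst) for the SF-36
# items that feed the scales but not the deficit schema; schema-backed
# items derive their emission labels from the schema mapping itself.
_EXTRA_SF36_EMIT: dict[str, tuple[tuple[str, ...], str, str]] = {
    **{f"q4{c}": (("No",), "Yes", "Yes") for c in "abcd"},
    **{f"q5{c}": (("No",), "Yes", "Yes") for c in "abc"},
    "q6": (("Not at all", "Slightly"), "Moderately", "Extremely"),
    "q7": (("None", "Very mild", "Mild"), "Moderate", "Very severe"),
    "q8": (("Not at all", "A little bit"), "Moderately", "Extremely"),
    "q10": (("None of the time", "A little of the time"), "Some of the time", "All of the time"),
}

_EQ5D_EMIT: dict[str, tuple[str, str, str]] = {
    "mobility": ("No Problems", "Some Problems", "Confined to bed"),
    "self_care": ("No Problems", "Some Problems", "Inability to wash or dress himself/herself"),
    "usual_activities": ("No Problems", "Some Problems", "Inability to perform usual activities"),
    "pain_discomfort": ("No pain", "Moderate pain", "Extreme pain"),
    "anxiety_depression": ("No Anxiety", "Moderate Anxiety", "Extreme Anxiety"),
}


def _emit_from_item(item: DeficitItem) -> tuple[tuple[str, ...], str, str]:
    """(zero-scoring labels, 0.5 label, 1.0 label) of a schema item."""
    if item.source_type == "eq5d":
        l1, l2, l3 = _EQ5D_EMIT[item.column]
        return (l1,), l2, l3
    if item.source_type == "comorbidity":
        return ("No",), "Yes", "Yes"
    good = tuple(k for k, v in item.mapping.items() if v == 0.0)
    mid = [k for k, v in item.mapping.items() if v == 0.5]
    worst = [k for k, v in item.mapping.items() if v == 1.0]
    return good, (mid[0] if mid else worst[0]), worst[0]


def _generation_columns() -> dict[str, tuple[tuple[str, ...], str, str]]:
    """Every generated column with its grade-to-label emission map."""
    cols: dict[str, tuple[tuple[str, ...], str, str]] = {}
    for item in build_retrospective_schema().items:
        cols[item.column] = _emit_from_item(item)
    for item in build_prospective_schema().items:
        cols.setdefault(item.column, _emit_from_item(item))
    cols["pain_discomfort"] = ((_EQ5D_EMIT["pain_discomfort"][0],),
                               _EQ5D_EMIT["pain_discomfort"][1],
                               _EQ5D_EMIT["pain_discomfort"][2])
    cols.update(_EXTRA_SF36_EMIT)
    return cols


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort of questionnaire records under the liability model.

    Returns a wide table with ``subject_id``, ``age``, ``age_stratum``,
    all 36 SF-36 items, the five EQ-5D dimensions, the 14 comorbidity
    flags and the 22 prospective-battery items.  A fixed seed gives a
    byte-identical table.
    """
    total = sum(spec.n_per_stratum)
    if total == 0:
        raise ValueError("cohort spec has zero total size")
    rng = np.random.default_rng(spec.seed)

    ages = np.concatenate(
        [
            rng.integers(lo, hi + 1, size=n)
            for (lo, hi), n in zip(AGE_STRATA, spec.n_per_stratum)
        ]
    )
    strata = np.concatenate(
        [np.full(n, lab) for lab, n in zip(_STRATUM_LABELS, spec.n_per_stratum)]
    )
    u = rng.normal(0.0, spec.liability_sd, size=total)
    with np.errstate(divide="ignore"):
        eta = logit(spec.baseline_prob) + spec.age_gradient * (ages - 50) + u
    p = expit(eta)

    cols = _generation_columns()
    data: dict[str, object] = {
        "subject_id": [f"S{i + 1:05d}" for i in range(total)],
        "age": ages,
        "age_stratum": strata,
    }
    for name, (good, mid, worst) in cols.items():
        deficit = rng.random(total) < p
        severe = rng.random(total) < spec.severe_frac
        pick = rng.integers(0, len(good), size=total)
        labels = np.array(good, dtype=object)[pick]
        labels[deficit & ~severe] = mid
        labels[deficit & severe] = worst
        if spec.missing_rate > 0:
            drop = rng.random(total) < spec.missing_rate
            labels[drop] = None
        data[name] = labels
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Model-implied quantities

def expected_fi(
    spec: CohortSpec,
    schema: DeficitSchema,
    age: float,
    quad_points: int = 61,
) -> float:
    """Model-implied mean FI at an age, integrating over the liability.

    E[FI | age] = E_u[ p(u) ] * mean_j c_j, where p(u) = expit(logit(p0)
    + gamma*(age-50) + u) and c_j = 0.5 + 0.5*severe_frac for items with
    a partial (0.5) category, 1 otherwise.  Assumes no missingness.
    """
    x, w = np.polynomial.hermite.hermgauss(quad_points)
    u = np.sqrt(2.0) * spec.liability_sd * x
    with np.errstate(divide="ignore"):
        p_mean = float(
            np.sum(w * expit(logit(spec.baseline_prob) + spec.age_gradient * (age - 50) + u))
            / np.sqrt(np.pi)
        )
    factors = [
        0.5 + 0.5 * spec.severe_frac if 0.5 in set(it.mapping.values()) else 1.0
        for it in schema.items
    ]
    return p_mean * float(np.mean(factors))


def implied_linear_slope(spec: CohortSpec, schema: DeficitSchema) -> float:
    """Population slope of the best linear fit of E[FI | age] on age.

    Uses the generator's age distribution (uniform integer ages within
    each stratum, weighted by stratum size), so it is the value a
    subject-level OLS slope converges to as the cohort grows.
    """
    ages, weights = [], []
    for (lo, hi), n in zip(AGE_STRATA, spec.n_per_stratum):
        span = np.arange(lo, hi + 1)
        ages.append(span)
        weights.append(np.full(span.size, n / span.size))
    a = np.concatenate(ages).astype(float)
    w = np.concatenate(weights)
    y = np.array([expected_fi(spec, schema, age) for age in a])
    abar = np.average(a, weights=w)
    ybar = np.average(y, weights=w)
    return float(np.sum(w * (a - abar) * (y - ybar)) / np.sum(w * (a - abar) ** 2))


# ---------------------------------------------------------------------------
# Post-dose trajectories

_DEFAULT_PF_DIP = {"non-frail": -2.1, "pre-frail": 0.0, "frail": -3.0}
_DEFAULT_UTILITY_DIP = {"non-frail": -0.045, "pre-frail": 0.0, "frail": -0.035}
# dip weight per day 0..7: transient Day-1 effect, recovered by Day 2
_DEFAULT_PROFILE = (0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def simulate_postdose_trajectories(
    cohort: pd.DataFrame,
    pf_dip: dict[str, float] | None = None,
    utility_dip: dict[str, float] | None = None,
    profile: tuple[float, ...] = _DEFAULT_PROFILE,
    noise_sd_pf: float = 0.5,
    noise_sd_utility: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Daily post-dose PF and utility records for a scored cohort.

    ``cohort`` needs columns ``subject_id``, ``category``, ``pf_baseline``
    and ``utility_baseline`` (the Day-0 values come from the cohort's own
    scored questionnaires).  Each category's reactogenicity effect is a
    dip added according to ``profile`` (weight per day, default a pure
    Day-1 dip), plus independent Gaussian noise.
    """
    if noise_sd_pf < 0 or noise_sd_utility < 0:
        raise ValueError("noise scales must be non-negative")
    required = {"subject_id", "category", "pf_baseline", "utility_baseline"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    pf_dip = _DEFAULT_PF_DIP if pf_dip is None else pf_dip
    utility_dip = _DEFAULT_UTILITY_DIP if utility_dip is None else utility_dip
    rng = np.random.default_rng(seed)
    n = len(cohort)
    w = np.asarray(profile, dtype=float)
    n_days = w.size
    dip_pf = cohort["category"].map(lambda c: pf_dip.get(c, 0.0)).to_numpy(float)
    dip_ut = cohort["category"].map(lambda c: utility_dip.get(c, 0.0)).to_numpy(float)
    pf = (
        cohort["pf_baseline"].to_numpy(float)[:, None]
        + dip_pf[:, None] * w[None, :]
        + rng.normal(0.0, noise_sd_pf, size=(n, n_days))
    )
    ut = (
        cohort["utility_baseline"].to_numpy(float)[:, None]
        + dip_ut[:, None] * w[None, :]
        + rng.normal(0.0, noise_sd_utility, size=(n, n_days))
    )
    return pd.DataFrame(
        {
            "subject_id": np.repeat(cohort["subject_id"].to_numpy(), n_days),
            "day": np.tile(np.arange(n_days), n),
            "pf": pf.ravel(),
            "utility": ut.ravel(),
        }
    )
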