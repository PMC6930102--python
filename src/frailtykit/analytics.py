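"""Validation analytics for paired frailty indices.

Three analyses are provided on top of the deficit engine:

* inter-index concordance — a 3x3 cross-tabulation of frailty categories
  from two indices, percent agreement, and Kendall's tau-b with its tie
  correction computed directly from the table's marginals;
* FI-versus-age trend fits — ordinary least squares of FI on age, either
  linear (FI = a + b*age) or exponential (log FI = a + b*age on positive
  FI values), at subject level or on mean FI per integer age;
* post-dose patient-reported-outcome trajectories — per-category daily
  means of the SF-36 physical-functioning score and the EQ-5D utility,
  with changes from Day 0 flagged against minimal clinically important
  differences (3.3 PF points, 0.074 utility by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .deficits import CATEGORIES

__all__ = [
    "PF_MCID",
    "UTILITY_MCID",
    "CrossTab3x3",
    "TauBResult",
    "ConcordanceResult",
    "AgeTrendFit",
    "crosstab",
    "agreement",
    "kendall_tau_b",
    "concordance",
    "fit_age_trend",
    "summarize_trajectories",
]

logger = logging.getLogger(__name__)

# Minimal clinically important differences for the trajectory summaries.
PF_MCID = 3.3
UTILITY_MCID = 0.074

_MCID_EPS = 1e-9  # |change| >= threshold is inclusive despite float rounding


@dataclass(frozen=True)
class CrossTab3x3:
    """3x3 contingency table of ordinal frailty categories.

    Rows index the first (e.g. retrospective) categorisation, columns the
    second (e.g. prospective), both ordered non-frail < pre-frail < frail.
    """

    counts: np.ndarray = field(repr=False)
    categories: tuple[str, str, str] = CATEGORIES

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", c)
        if c.shape != (3, 3):
            raise ValueError(f"expected a 3x3 table, got shape {c.shape}")
        if (c < 0).any():
            raise ValueError("cell counts must be non-negative")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self, percent: bool = False) -> pd.DataFrame:
        """Counts (or row percentages) with marginal totals, table-style."""
        df = pd.DataFrame(self.counts, index=self.categories, columns=self.categories)
        df["Total"] = df.sum(axis=1)
        df.loc["Total"] = df.sum(axis=0)
        if percent:
            denom = df["Total"].to_numpy()[:, None]
            with np.errstate(invalid="ignore", divide="ignore"):
                df = 100.0 * df / denom
        return df

    def to_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Expand the table back to paired ordinal label vectors (0/1/2)."""
        rows, cols = np.nonzero(self.counts)
        reps = self.counts[rows, cols]
        return np.repeat(rows, reps), np.repeat(cols, reps)


def crosstab(
    cats_a: Sequence[str],
    cats_b: Sequence[str],
    categories: tuple[str, str, str] = CATEGORIES,
) -> CrossTab3x3:
    """Cross-tabulate two equal-length category vectors.

    Raises on unequal lengths, empty input or an unknown category label.
    """
    a = pd.Series(list(cats_a))
    b = pd.Series(list(cats_b))
    if len(a) != len(b):
        raise ValueError(f"category vectors differ in length: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("cannot cross-tabulate empty category vectors")
    for name, v in (("first", a), ("second", b)):
        unknown = set(v) - set(categories)
        if unknown:
            raise ValueError(f"unknown categories in {name} vector: {sorted(unknown)}")
    counts = np.zeros((3, 3), dtype=np.int64)
    idx = {c: i for i, c in enumerate(categories)}
    for x, y in zip(a, b):
        counts[idx[x], idx[y]] += 1
    return CrossTab3x3(counts=counts, categories=categories)


def agreement(ct: CrossTab3x3) -> tuple[int, float]:
    """Diagonal agreement: (count, fraction of the grand total)."""
    total = ct.grand_total
    if total == 0:
        raise ValueError("agreement undefined for an empty table")
    count = int(np.trace(ct.counts))
    return count, count / total


@dataclass(frozen=True)
class TauBResult:
    """Kendall's tau-b with its two-sided p-value.

    ``tau`` is None for a degenerate table (all mass in one row or
    column), where the tie correction leaves nothing to rank.
    """

    tau: float | None
    p_value: float | None
    z: float | None
    n_concordant: int
    n_discordant: int
    method: str
    note: str = ""


def _pair_counts(counts: np.ndarray) -> tuple[int, int]:
    """Concordant and discordant pair counts of an ordinal r x c table."""
    c = d = 0
    r, s = counts.shape
    for i in range(r):
        for j in range(s):
            nij = int(counts[i, j])
            if nij == 0:
                continue
            c += nij * int(counts[i + 1 :, j + 1 :].sum())
            d += nij * int(counts[i + 1 :, :j].sum())
    return c, d


def kendall_tau_b(
    ct: CrossTab3x3,
    method: str = "normal",
    n_resamples: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> TauBResult:
    """Kendall's tau-b of an ordinal 3x3 table, from its marginals.

    tau_b = (C - D) / sqrt((n0 - n1)(n0 - n2)) with C/D the concordant/
    discordant pair counts, n0 = n(n-1)/2 and n1, n2 the tied-pair counts
    from the row and column marginals.  The p-value uses the standard
    tie-corrected normal approximation of the null distribution of C - D;
    ``method="permutation"`` draws a Monte Carlo permutation null instead
    (grand totals <= 200 only, where it is affordable).
    """
    n = ct.grand_total
    cc, dd = _pair_counts(ct.counts)
    n0 = n * (n - 1) // 2
    t = ct.row_totals.astype(np.int64)
    u = ct.col_totals.astype(np.int64)
    n1 = int((t * (t - 1) // 2).sum())
    n2 = int((u * (u - 1) // 2).sum())
    if n0 == n1 or n0 == n2:
        return TauBResult(
            None, None, None, cc, dd, method,
            note="degenerate table: all mass in one row or column",
        )
    tau = (cc - dd) / np.sqrt(float(n0 - n1) * float(n0 - n2))
    if method == "normal":
        # Python ints: the tie polynomials overflow int64 for large tables
        tl, ul = [int(x) for x in t], [int(x) for x in u]
        vt0 = n * (n - 1) * (2 * n + 5)
        vt = sum(x * (x - 1) * (2 * x + 5) for x in tl)
        vu = sum(x * (x - 1) * (2 * x + 5) for x in ul)
        v1 = (
            sum(x * (x - 1) for x in tl) * sum(x * (x - 1) for x in ul)
        ) / (2.0 * n * (n - 1))
        v2 = (
            sum(x * (x - 1) * (x - 2) for x in tl)
            * sum(x * (x - 1) * (x - 2) for x in ul)
            / (9.0 * n * (n - 1) * (n - 2))
        ) if n > 2 else 0.0
        var = (vt0 - vt - vu) / 18.0 + v1 + v2
        z = (cc - dd) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
        return TauBResult(float(tau), float(p), float(z), cc, dd, "normal")
    if method == "permutation":
        if n > 200:
            raise ValueError("permutation p-value supported for grand totals <= 200")
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        a, b = ct.to_pairs()
        observed = abs(cc - dd)
        hits = 0
        for _ in range(n_resamples):
            perm = gen.permutation(b)
            tau_p = stats.kendalltau(a, perm).statistic
            # marginals (hence tie counts) are fixed under permutation, so
            # C - D can be recovered from tau-b directly
            c_minus_d = tau_p * np.sqrt(float(n0 - n1) * float(n0 - n2))
            if abs(c_minus_d) >= observed - 1e-9:
                hits += 1
        p = (hits + 1) / (n_resamples + 1)
        return TauBResult(float(tau), float(p), None, cc, dd, "permutation")
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class ConcordanceResult:
    """Cross-tab, percent agreement and tau-b for two categorisations."""

    crosstab: CrossTab3x3
    agreement_count: int
    agreement_fraction: float
    tau: TauBResult

    def as_dict(self) -> dict:
        return {
            "n": self.crosstab.grand_total,
            "counts": self.crosstab.counts.tolist(),
            "categories": list(self.crosstab.categories),
            "agreement_count": self.agreement_count,
            "agreement_percent": 100.0 * self.agreement_fraction,
            "tau_b": self.tau.tau,
            "p_value": self.tau.p_value,
            "tau_method": self.tau.method,
            "note": self.tau.note,
        }


def concordance(
    cats_a: Sequence[str] | CrossTab3x3,
    cats_b: Sequence[str] | None = None,
    method: str = "normal",
) -> ConcordanceResult:
    """Full concordance report from label vectors or a ready-made table."""
    ct = cats_a if isinstance(cats_a, CrossTab3x3) else crosstab(cats_a, cats_b)
    count, frac = agreement(ct)
    return ConcordanceResult(ct, count, frac, kendall_tau_b(ct, method=method))


# ---------------------------------------------------------------------------
# FI vs age trends

@dataclass(frozen=True)
class AgeTrendFit:
    """An OLS fit of FI (or log FI) on age."""

    form: str  # "linear" | "exponential"
    intercept: float
    slope: float
    r_squared: float
    p_value: float
    granularity: str  # "subject" | "mean-by-age"
    n_obs: int
    n_excluded: int  # non-positive FI dropped by the exponential form
    age_range: tuple[float, float]

    def predict(self, age: float) -> tuple[float, bool]:
        """Predicted FI at an age, plus an extrapolation flag.

        The flag is True when ``age`` lies outside the fitted age range.
        """
        linear = self.intercept + self.slope * age
        value = linear if self.form == "linear" else float(np.exp(linear))
        extrapolated = not (self.age_range[0] <= age <= self.age_range[1])
        return value, extrapolated


def fit_age_trend(
    ages: Sequence[float],
    fi: Sequence[float],
    form: str = "linear",
    granularity: str = "subject",
) -> AgeTrendFit:
    """Least-squares trend of frailty index on age.

    ``form="linear"`` fits FI = a + b*age; ``form="exponential"`` fits
    log FI = a + b*age on the records with FI > 0 (the excluded count is
    reported and logged).  ``granularity="mean-by-age"`` first averages FI
    within each integer year of age, mirroring a mean-FI-per-age scatter;
    the default fits subject-level points.
    """
    df = pd.DataFrame({"age": np.asarray(ages, float), "fi": np.asarray(fi, float)}).dropna()
    if df["age"].nunique() < 3:
        raise ValueError("age-trend fit requires at least 3 distinct ages")
    if granularity == "mean-by-age":
        df = (
            df.assign(age=df["age"].round().astype(int))
            .groupby("age", as_index=False)["fi"].mean()
        )
    elif granularity != "subject":
        raise ValueError(f"unknown granularity {granularity!r}")
    n_excluded = 0
    y = df["fi"]
    if form == "exponential":
        keep = y > 0
        n_excluded = int((~keep).sum())
        if n_excluded:
            logger.info("exponential fit: dropped %d records with FI <= 0", n_excluded)
        df = df[keep]
        y = np.log(df["fi"])
    elif form != "linear":
        raise ValueError(f"unknown form {form!r}")
    if df["age"].nunique() < 3:
        raise ValueError("fewer than 3 distinct ages remain after filtering")
    X = sm.add_constant(df["age"].to_numpy())
    res = sm.OLS(np.asarray(y, float), X).fit()
    return AgeTrendFit(
        form=form,
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        r_squared=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        granularity=granularity,
        n_obs=int(res.nobs),
        n_excluded=n_excluded,
        age_range=(float(df["age"].min()), float(df["age"].max())),
    )


# ---------------------------------------------------------------------------
# Post-dose PRO trajectories

def summarize_trajectories(
    daily: pd.DataFrame,
    categories: Mapping[str, str] | pd.Series,
    pf_mcid: float = PF_MCID,
    utility_mcid: float = UTILITY_MCID,
) -> pd.DataFrame:
    """Per-category daily means of PF and utility with MCID flags.

    ``daily`` is long-format with columns ``subject_id``, ``day`` (0..7),
    ``pf`` and ``utility``; ``categories`` maps subject id to frailty
    category.  Changes are computed from the Day-0 mean of the same
    category; ``*_mcid`` flags whether |change| reaches the clinically
    relevant threshold (inclusive).  Categories with no subjects are
    omitted with a logged notice.
    """
    required = {"subject_id", "day", "pf", "utility"}
    missing = required - set(daily.columns)
    if missing:
        raise ValueError(f"daily table missing columns: {sorted(missing)}")
    cats = pd.Series(dict(categories)) if not isinstance(categories, pd.Series) else categories
    df = daily.copy()
    df["category"] = df["subject_id"].map(cats)
    unmapped = df["category"].isna()
    if unmapped.any():
        logger.warning("dropping %d daily rows with no frailty category", int(unmapped.sum()))
        df = df[~unmapped]
    present = set(df["category"])
    for cat in CATEGORIES:
        if cat not in present:
            logger.info("trajectory summary: no subjects in category %r, omitted", cat)
    grouped = (
        df.groupby(["category", "day"], observed=True)
        .agg(n=("subject_id", "nunique"), mean_pf=("pf", "mean"), mean_utility=("utility", "mean"))
        .reset_index()
    )
    out = []
    for cat in [c for c in CATEGORIES if c in present]:
        block = grouped[grouped["category"] == cat].sort_values("day").copy()
        base = block[block["day"] == 0]
        if base.empty:
            raise ValueError(f"category {cat!r}: Day 0 required to compute changes")
        pf0 = float(base["mean_pf"].iloc[0])
        ut0 = float(base["mean_utility"].iloc[0])
        block["pf_change"] = block["mean_pf"] - pf0
        block["utility_change"] = block["mean_utility"] - ut0
        block["pf_mcid"] = block["pf_change"].abs() >= pf_mcid - _MCID_EPS
        block["utility_mcid"] = block["utility_change"].abs() >= utility_mcid - _MCID_EPS
        out.append(block)
    return pd.concat(out, ignore_index=True)
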