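"""Deficit-accumulation frailty indices.

In the deficit-accumulation model (Mitnitski & Rockwood), frailty is
quantified as the proportion of health deficits an individual carries
out of the deficits assessed: FI = deficit score / n, where each deficit
contributes 0 (absent), 0.5 (partially present) or 1 (present) and n is
the number of non-missing components.  Individuals are categorised as
non-frail (FI <= 0.08), pre-frail (0.08 < FI <= 0.25) or frail
(FI > 0.25).

Two schemas are provided:

* a fully specified retrospective 43-item index built from pre-vaccination
  SF-36 items, four EQ-5D-3L dimensions and 14 medical-history
  comorbidities (maximum contributions 25 + 4 + 14 = 43);
* a configurable engine for a prospective 36-item battery (disability,
  cognition, self-rated health, physical status, depression/exhaustion,
  multimorbidity), driven by a declarative YAML/JSON schema because the
  instrument-level cut-points are study-specific.

The module also runs saturation diagnostics: a candidate deficit that is
already highly prevalent in the youngest age stratum cannot discriminate
frailty and is flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .eq5d import parse_level
from .sf36 import SF36_ITEMS, IllegalResponseError, normalize_label

__all__ = [
    "CATEGORIES",
    "DEFAULT_CUTOFFS",
    "DEFAULT_COMORBIDITIES",
    "DeficitItem",
    "DeficitSchema",
    "DeficitVector",
    "FrailtyResult",
    "SchemaError",
    "build_retrospective_schema",
    "build_prospective_schema",
    "load_schema",
    "map_deficits",
    "map_deficits_frame",
    "compute_fi",
    "compute_fi_frame",
    "categorize",
    "saturation_check",
]

logger = logging.getLogger(__name__)

CATEGORIES: tuple[str, str, str] = ("non-frail", "pre-frail", "frail")
DEFAULT_CUTOFFS: tuple[float, float] = (0.08, 0.25)
ALLOWED_SCORES = frozenset({0.0, 0.5, 1.0})

# The trial assessed 14 medical-history conditions (multimorbidity deficits,
# one point each).  Only "high blood pressure" is named in the available
# text; the remaining condition names are this package's assumption and are
# configurable.
DEFAULT_COMORBIDITIES: tuple[str, ...] = (
    "high_blood_pressure",
    "diabetes",
    "cancer",
    "chronic_lung_disease",
    "myocardial_infarction",
    "congestive_heart_failure",
    "angina",
    "asthma",
    "arthritis",
    "stroke",
    "kidney_disease",
    "liver_disease",
    "thyroid_disease",
    "osteoporosis",
)

_SOURCE_TYPES = ("sf36", "eq5d", "comorbidity", "battery")

_PRESENT = frozenset({"yes", "present", "true", "y", "1"})
_ABSENT = frozenset({"no", "absent", "false", "n", "0"})


class SchemaError(ValueError):
    """A deficit schema that violates its structural contract."""


def _is_missing(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def parse_comorbidity(name: str, value: object) -> str | None:
    """Canonical present/absent/None for a comorbidity flag."""
    if _is_missing(value):
        return None
    if isinstance(value, (bool, np.bool_)):
        return "present" if value else "absent"
    if isinstance(value, (int, float, np.integer, np.floating)):
        if float(value) in (0.0, 1.0):
            return "present" if value else "absent"
        raise IllegalResponseError(name, value)
    key = normalize_label(value)
    if key in _PRESENT:
        return "present"
    if key in _ABSENT:
        return "absent"
    raise IllegalResponseError(name, value)


@dataclass(frozen=True)
class DeficitItem:
    """One unit-maximum deficit: a response-to-score mapping in {0, 0.5, 1}.

    ``source_type`` says where the response comes from (an SF-36 item, an
    EQ-5D dimension, a comorbidity flag or a prospective-battery
    instrument); ``column`` is the input column holding it.
    """

    id: str
    source_type: str
    column: str
    mapping: Mapping[str, float]
    note: str = ""

    def __post_init__(self) -> None:
        if self.source_type not in _SOURCE_TYPES:
            raise SchemaError(f"item {self.id!r}: unknown source type {self.source_type!r}")
        if not self.mapping:
            raise SchemaError(f"item {self.id!r}: empty mapping")
        scores = set(float(v) for v in self.mapping.values())
        if not scores <= ALLOWED_SCORES:
            bad = sorted(scores - ALLOWED_SCORES)
            raise SchemaError(f"item {self.id!r}: scores {bad} outside {{0, 0.5, 1}}")
        if max(scores) != 1.0:
            raise SchemaError(f"item {self.id!r}: maximum contribution must be 1")
        object.__setattr__(
            self, "mapping", {normalize_label(k): float(v) for k, v in self.mapping.items()}
        )
        if self.source_type == "sf36":
            legal = set(SF36_ITEMS.get(self.column, {}))
            if not legal:
                raise SchemaError(f"item {self.id!r}: unknown SF-36 item {self.column!r}")
            uncovered = legal - set(self.mapping)
            if uncovered:
                raise SchemaError(
                    f"item {self.id!r}: mapping does not cover levels {sorted(uncovered)}"
                )

    def score(self, value: object) -> float | None:
        """Deficit score of one raw response; ``None`` when missing."""
        if self.source_type == "eq5d":
            lvl = parse_level(self.column, value)
            return None if lvl is None else self.mapping[str(lvl)]
        if self.source_type == "comorbidity":
            state = parse_comorbidity(self.column, value)
            return None if state is None else self.mapping[state]
        if _is_missing(value):
            return None
        key = normalize_label(value)
        if key not in self.mapping:
            raise IllegalResponseError(self.id, value)
        return self.mapping[key]


@dataclass(frozen=True)
class DeficitSchema:
    """An ordered list of unit-maximum deficits plus category cutoffs."""

    name: str
    items: tuple[DeficitItem, ...]
    cutoffs: tuple[float, float] = DEFAULT_CUTOFFS

    def __post_init__(self) -> None:
        ids = [it.id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate item ids: {dupes}")
        lo, hi = self.cutoffs
        if not (0.0 < lo < hi < 1.0):
            raise SchemaError(f"cutoffs must be strictly increasing in (0, 1): {self.cutoffs}")

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.id for it in self.items)

    def max_contribution(self, source_type: str | None = None) -> float:
        """Sum of item maxima (each 1), optionally for one source type."""
        return float(
            sum(1 for it in self.items if source_type is None or it.source_type == source_type)
        )


@dataclass(frozen=True)
class DeficitVector:
    """Per-item deficit scores for one subject, aligned to a schema."""

    schema_name: str
    item_ids: tuple[str, ...]
    scores: np.ndarray = field(repr=False)  # float array, NaN = missing

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", s)
        if s.shape != (len(self.item_ids),):
            raise ValueError("scores not aligned to item ids")

    @property
    def total(self) -> float:
        return float(np.nansum(self.scores))

    @property
    def n_answered(self) -> int:
        return int(np.sum(~np.isnan(self.scores)))


@dataclass(frozen=True)
class FrailtyResult:
    """FI = deficit sum / non-missing count, with its category."""

    schema_name: str
    deficit_sum: float
    n_items: int
    fi: float | None
    category: str | None


# ---------------------------------------------------------------------------
# Schema construction

def _table1_sf36_items() -> list[DeficitItem]:
    """SF-36 contributions to the retrospective index (25 unit deficits)."""
    zero = 0.0
    items: list[DeficitItem] = []
    items.append(
        DeficitItem(
            id="sf36_q1",
            source_type="sf36",
            column="q1",
            mapping={
                "Poor": 1, "Fair": 0.5, "Good": zero, "Very good": zero, "Excellent": zero,
            },
            note="general health rating",
        )
    )
    true_is_deficit = {
        "Definitely true": 1, "Mostly true": 0.5,
        "Don't know": zero, "Mostly false": zero, "Definitely false": zero,
    }
    false_is_deficit = {
        "Definitely false": 1, "Mostly false": 0.5,
        "Don't know": zero, "Mostly true": zero, "Definitely true": zero,
    }
    for sub in "abcd":
        items.append(
            DeficitItem(
                id=f"sf36_q11{sub}",
                source_type="sf36",
                column=f"q11{sub}",
                mapping=true_is_deficit if sub in "ac" else false_is_deficit,
                note="general health beliefs",
            )
        )
    for sub in "abcdefghij":
        items.append(
            DeficitItem(
                id=f"sf36_q3{sub}",
                source_type="sf36",
                column=f"q3{sub}",
                mapping={"Limited a lot": 1, "Limited a little": 0.5, "Not limited at all": zero},
                note="physical functioning",
            )
        )
    none_is_deficit = {
        "None of the time": 1, "A little of the time": 0.5,
        "Some of the time": zero, "Most of the time": zero, "All of the time": zero,
    }
    all_is_deficit = {
        "All of the time": 1, "Most of the time": 0.5,
        "Some of the time": zero, "A little of the time": zero, "None of the time": zero,
    }
    for sub in "abcdefghi":
        items.append(
            DeficitItem(
                id=f"sf36_q9{sub}",
                source_type="sf36",
                column=f"q9{sub}",
                mapping=none_is_deficit if sub in "adeh" else all_is_deficit,
                note="vitality and mental health",
            )
        )
    items.append(
        DeficitItem(
            id="sf36_q2",
            source_type="sf36",
            column="q2",
            mapping={
                "Much worse": 1, "Somewhat worse": 0.5,
                "Same": zero, "Somewhat better": zero, "Much better": zero,
            },
            note="health change vs one week before",
        )
    )
    return items


def build_retrospective_schema(
    comorbidities: Sequence[str] = DEFAULT_COMORBIDITIES,
    cutoffs: tuple[float, float] = DEFAULT_CUTOFFS,
) -> DeficitSchema:
    """The 43-item retrospective frailty index.

    14 comorbidity deficits (1 point each) + 25 SF-36 deficits + 4 EQ-5D
    deficits (mobility, anxiety/depression, self-care, usual activities;
    pain/discomfort is not a component).
    """
    if len(comorbidities) != 14:
        raise SchemaError(f"expected 14 comorbidities, got {len(comorbidities)}")
    items: list[DeficitItem] = [
        DeficitItem(
            id=f"cmb_{name}",
            source_type="comorbidity",
            column=name,
            mapping={"present": 1, "absent": 0.0},
            note="medical history condition",
        )
        for name in comorbidities
    ]
    items.extend(_table1_sf36_items())
    graded3 = {"1": 0.0, "2": 0.5, "3": 1}
    for dim in ("mobility", "anxiety_depression", "self_care", "usual_activities"):
        items.append(
            DeficitItem(
                id=f"eq5d_{dim}", source_type="eq5d", column=dim, mapping=graded3,
                note="worst level = 1, middle = 0.5",
            )
        )
    return DeficitSchema(name="retrospective_43", items=tuple(items), cutoffs=cutoffs)


def load_schema(source: str | Path, expected_n: int | None = None) -> DeficitSchema:
    """Load and validate a deficit schema from a YAML/JSON config file.

    The file declares ``name``, optional ``cutoffs`` and an ``items`` list
    of ``{id, source, column?, mapping, note?}`` entries.  Every
    structural violation (wrong item count, score outside {0, 0.5, 1},
    missing mapping) is rejected naming the offending item.
    """
    payload = yaml.safe_load(Path(source).read_text())
    if not isinstance(payload, dict) or "items" not in payload:
        raise SchemaError(f"{source}: schema config must declare an 'items' list")
    items = []
    for entry in payload["items"]:
        try:
            items.append(
                DeficitItem(
                    id=str(entry["id"]),
                    source_type=str(entry["source"]),
                    column=str(entry.get("column", entry["id"])),
                    mapping=entry["mapping"],
                    note=str(entry.get("note", "")),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"item entry {entry!r}: missing field {exc}") from None
    cutoffs = tuple(payload.get("cutoffs", DEFAULT_CUTOFFS))
    schema = DeficitSchema(
        name=str(payload.get("name", Path(source).stem)), items=tuple(items), cutoffs=cutoffs
    )
    if expected_n is not None and schema.n_items != expected_n:
        raise SchemaError(
            f"schema {schema.name!r} has {schema.n_items} items, expected {expected_n}"
        )
    return schema


def build_prospective_schema(config: str | Path | None = None) -> DeficitSchema:
    """The 36-item prospective battery schema (packaged default or custom file).

    The packaged default encodes the battery's domain structure —
    disability (14), cognition (1), self-rated health and health change
    (2), physical status (4), depression/exhaustion (1), multimorbidity
    (14) — with assumed instrument cut-points, since those are
    study-specific.  Any 36-item config with complete {0, 0.5, 1}
    mappings is accepted.
    """
    if config is None:
        ref = resources.files("frailtykit.data") / "prospective_fi.yaml"
        with resources.as_file(ref) as path:
            return load_schema(path, expected_n=36)
    return load_schema(config, expected_n=36)


# ---------------------------------------------------------------------------
# Scoring

def map_deficits(record: Mapping[str, object], schema: DeficitSchema) -> DeficitVector:
    """Score one subject's record against a schema.

    Unanswered source responses propagate to missing item scores; an
    illegal response label raises :class:`IllegalResponseError` naming the
    item and label.
    """
    scores = np.array(
        [np.nan if (s := it.score(record.get(it.column))) is None else s for it in schema.items],
        dtype=float,
    )
    return DeficitVector(schema_name=schema.name, item_ids=schema.item_ids, scores=scores)


def map_deficits_frame(df: pd.DataFrame, schema: DeficitSchema) -> pd.DataFrame:
    """Per-item deficit scores for a whole table (NaN = missing)."""
    out: dict[str, pd.Series] = {}
    for it in schema.items:
        if it.column in df.columns:
            col = df[it.column]
            out[it.id] = col.map(
                lambda v, item=it: np.nan if (s := item.score(v)) is None else s
            ).astype(float)
        else:
            out[it.id] = pd.Series(np.nan, index=df.index)
    return pd.DataFrame(out, index=df.index)


def categorize(fi: float, cutoffs: tuple[float, float] = DEFAULT_CUTOFFS) -> str:
    """Frailty category of an FI value.

    Boundary semantics: FI <= 0.08 is non-frail; 0.08 < FI <= 0.25 is
    pre-frail; FI > 0.25 is frail (<= at each cutoff belongs to the lower
    category).
    """
    if not (0.0 <= fi <= 1.0):
        raise ValueError(f"FI must lie in [0, 1], got {fi!r}")
    lo, hi = cutoffs
    if fi <= lo:
        return CATEGORIES[0]
    if fi <= hi:
        return CATEGORIES[1]
    return CATEGORIES[2]


def compute_fi(
    v: DeficitVector,
    floor: float = 0.8,
    cutoffs: tuple[float, float] = DEFAULT_CUTOFFS,
) -> FrailtyResult:
    """FI = deficit sum / non-missing count, missing below the completeness floor.

    ``floor`` is the minimum answered fraction n/N for a valid FI (0.8 by
    common frailty-index practice; configurable).
    """
    n = v.n_answered
    total = v.total
    n_total = len(v.item_ids)
    if n == 0 or (n_total > 0 and n / n_total < floor):
        logger.info(
            "FI undefined: %d/%d items answered (< floor %.2f)", n, n_total, floor
        )
        return FrailtyResult(v.schema_name, total, n, None, None)
    fi = total / n
    return FrailtyResult(v.schema_name, total, n, fi, categorize(fi, cutoffs))


def compute_fi_frame(
    scores: pd.DataFrame,
    schema: DeficitSchema,
    floor: float = 0.8,
) -> pd.DataFrame:
    """Per-subject deficit sum, n, FI and category from an item-score table."""
    block = scores[list(schema.item_ids)]
    n = block.notna().sum(axis=1)
    total = block.sum(axis=1)  # pandas skips NaN
    fi = total / n
    fi[(n == 0) | (n / schema.n_items < floor)] = np.nan
    lo, hi = schema.cutoffs
    category = pd.Series(pd.NA, index=scores.index, dtype="object")
    category[fi <= lo] = CATEGORIES[0]
    category[(fi > lo) & (fi <= hi)] = CATEGORIES[1]
    category[fi > hi] = CATEGORIES[2]
    return pd.DataFrame(
        {
            "deficit_sum": total,
            "n_items": n,
            "fi": fi,
            "category": category,
            "schema": schema.name,
        },
        index=scores.index,
    )


# ---------------------------------------------------------------------------
# Saturation diagnostics

def saturation_check(
    scores: pd.DataFrame,
    ages: pd.Series,
    young_range: tuple[float, float] = (50, 59),
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Per-item deficit prevalence overall and in the youngest stratum.

    A deficit is "saturated" when its prevalence (score > 0 among
    answered) in the youngest age stratum reaches ``threshold``: such an
    item is too common at younger ages to discriminate frailty.  With an
    empty youngest stratum the flags are not evaluable and reported as
    such.
    """
    ages = pd.Series(ages).reindex(scores.index)
    lo, hi = young_range
    young = (ages >= lo) & (ages <= hi)
    answered = scores.notna()
    positive = scores.gt(0) & answered
    prev_all = positive.sum() / answered.sum()
    n_young = int(young.sum())
    report = pd.DataFrame(
        {
            "prevalence_overall": prev_all,
            "n_young": n_young,
        }
    )
    if n_young == 0:
        logger.warning("saturation check: youngest stratum %s is empty", young_range)
        report["prevalence_young"] = np.nan
        report["saturated"] = pd.NA
        report["status"] = "not-evaluable"
        return report
    prev_young = positive[young].sum() / answered[young].sum()
    report["prevalence_young"] = prev_young
    report["saturated"] = prev_young >= threshold
    report["status"] = "ok"
    return report
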