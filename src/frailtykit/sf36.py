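"""Scoring of SF-36 questionnaire responses into the eight 0-100 scales.

The SF-36 is a 36-item generic health survey yielding eight scales:
physical functioning (PF), role limitations due to physical health (RP),
bodily pain (BP), general health (GH), vitality (VT), social functioning
(SF), role limitations due to emotional problems (RE), and mental health
(MH).  Scoring follows the public-domain RAND-36 convention: each item is
recoded to a 0-100 value (higher = better health, with the standard item
reversals), and a scale score is the mean of its answered items.

A scale is treated as missing when more than half of its items are
missing; otherwise averaging over the answered items is equivalent to
person-mean imputation of the missing ones.

Item codes follow the usual questionnaire layout: ``q1``, ``q2``,
``q3a``..``q3j``, ``q4a``..``q4d``, ``q5a``..``q5c``, ``q6``, ``q7``,
``q8``, ``q9a``..``q9i``, ``q10``, ``q11a``..``q11d``.  The q9 battery
uses the five-level response set (All / Most / Some / A little / None of
the time).  ``q2`` (health transition) is legal input but belongs to no
scale.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, fields
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SF36Scales",
    "IllegalResponseError",
    "SF36_ITEMS",
    "SF36_SCALES",
    "normalize_label",
    "recode_item",
    "score_sf36",
    "score_sf36_frame",
]


class IllegalResponseError(ValueError):
    """A response label outside the item's legal category set."""

    def __init__(self, item: str, label: object):
        self.item = item
        self.label = label
        super().__init__(f"illegal response for item {item!r}: {label!r}")


_WS = re.compile(r"\s+")


def normalize_label(label: object) -> str:
    """Canonical form of a category label: lowercase, collapsed whitespace,
    straight apostrophes."""
    s = str(label).replace("’", "'").replace("‘", "'")
    return _WS.sub(" ", s).strip().lower()


def _recode(pairs: Iterable[tuple[str, float]]) -> dict[str, float]:
    return {normalize_label(k): float(v) for k, v in pairs}


_EVG = _recode(
    [("Excellent", 100), ("Very good", 75), ("Good", 50), ("Fair", 25), ("Poor", 0)]
)
_TRANSITION = _recode(
    [
        ("Much better", 100),
        ("Somewhat better", 75),
        ("Same", 50),
        ("Somewhat worse", 25),
        ("Much worse", 0),
    ]
)
_LIMITED = _recode(
    [("Limited a lot", 0), ("Limited a little", 50), ("Not limited at all", 100)]
)
_YESNO = _recode([("Yes", 0), ("No", 100)])
_INTERFERE = _recode(
    [
        ("Not at all", 100),
        ("Slightly", 75),
        ("Moderately", 50),
        ("Quite a bit", 25),
        ("Extremely", 0),
    ]
)
_PAIN_MAG = _recode(
    [
        ("None", 100),
        ("Very mild", 80),
        ("Mild", 60),
        ("Moderate", 40),
        ("Severe", 20),
        ("Very severe", 0),
    ]
)
_PAIN_INTERFERE = _recode(
    [
        ("Not at all", 100),
        ("A little bit", 75),
        ("Moderately", 50),
        ("Quite a bit", 25),
        ("Extremely", 0),
    ]
)
_TIME_POS = _recode(  # positively worded: feeling good all of the time is best
    [
        ("All of the time", 100),
        ("Most of the time", 75),
        ("Some of the time", 50),
        ("A little of the time", 25),
        ("None of the time", 0),
    ]
)
_TIME_NEG = {k: 100.0 - v for k, v in _TIME_POS.items()}
_TRUE_BAD = _recode(  # statement describes poor health; "definitely true" is worst
    [
        ("Definitely true", 0),
        ("Mostly true", 25),
        ("Don't know", 50),
        ("Mostly false", 75),
        ("Definitely false", 100),
    ]
)
_TRUE_GOOD = {k: 100.0 - v for k, v in _TRUE_BAD.items()}

# q9 items feeling states: a=pep, d=calm, e=energy, h=happy are positive;
# b=nervous, c=down in the dumps, f=downhearted, g=worn out, i=tired are negative.
_Q9_POSITIVE = ("q9a", "q9d", "q9e", "q9h")

SF36_ITEMS: dict[str, dict[str, float]] = {
    "q1": _EVG,
    "q2": _TRANSITION,
    **{f"q3{c}": _LIMITED for c in "abcdefghij"},
    **{f"q4{c}": _YESNO for c in "abcd"},
    **{f"q5{c}": _YESNO for c in "abc"},
    "q6": _INTERFERE,
    "q7": _PAIN_MAG,
    "q8": _PAIN_INTERFERE,
    **{f"q9{c}": (_TIME_POS if f"q9{c}" in _Q9_POSITIVE else _TIME_NEG) for c in "abcdefghi"},
    "q10": _recode(
        [
            ("All of the time", 0),
            ("Most of the time", 25),
            ("Some of the time", 50),
            ("A little of the time", 75),
            ("None of the time", 100),
        ]
    ),
    "q11a": _TRUE_BAD,
    "q11b": _TRUE_GOOD,
    "q11c": _TRUE_BAD,
    "q11d": _TRUE_GOOD,
}

SF36_SCALES: dict[str, tuple[str, ...]] = {
    "physical_functioning": tuple(f"q3{c}" for c in "abcdefghij"),
    "role_physical": tuple(f"q4{c}" for c in "abcd"),
    "bodily_pain": ("q7", "q8"),
    "general_health": ("q1", "q11a", "q11b", "q11c", "q11d"),
    "vitality": ("q9a", "q9e", "q9g", "q9i"),
    "social_functioning": ("q6", "q10"),
    "role_emotional": tuple(f"q5{c}" for c in "abc"),
    "mental_health": ("q9b", "q9c", "q9d", "q9f", "q9h"),
}


@dataclass(frozen=True)
class SF36Scales:
    """The eight SF-36 scale scores, each 0-100 or ``None`` if not scorable."""

    physical_functioning: float | None
    role_physical: float | None
    bodily_pain: float | None
    general_health: float | None
    vitality: float | None
    social_functioning: float | None
    role_emotional: float | None
    mental_health: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _is_missing(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def recode_item(item: str, value: object) -> float | None:
    """0-100 recode of one item response; ``None`` for a missing response.

    Raises
    ------
    KeyError
        If ``item`` is not an SF-36 item code.
    IllegalResponseError
        If the response is not in the item's legal category set.
    """
    table = SF36_ITEMS[item]
    if _is_missing(value):
        return None
    key = normalize_label(value)
    if key not in table:
        raise IllegalResponseError(item, value)
    return table[key]


def score_sf36(resp: Mapping[str, object]) -> SF36Scales:
    """Score one subject's SF-36 responses into the eight scales.

    ``resp`` maps item codes to category labels; absent keys, ``None``,
    NaN and empty strings all count as missing.  Unknown keys are ignored
    so a full questionnaire row (with id/age columns) can be passed as-is
    provided no extra column collides with an item code.
    """
    recoded: dict[str, float | None] = {
        item: recode_item(item, resp.get(item)) for item in SF36_ITEMS
    }
    scores: dict[str, float | None] = {}
    for scale, items in SF36_SCALES.items():
        vals = [recoded[i] for i in items if recoded[i] is not None]
        n_missing = len(items) - len(vals)
        # more than half missing -> scale not scorable
        scores[scale] = float(np.mean(vals)) if n_missing <= len(items) / 2 else None
    return SF36Scales(**scores)


def score_sf36_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised scale scoring of a wide table (one row per subject-visit).

    Missing item columns are treated as entirely unanswered.  Returns a
    DataFrame with the eight scale columns (NaN where not scorable),
    indexed like ``df``.
    """
    recoded: dict[str, pd.Series] = {}
    for item, table in SF36_ITEMS.items():
        if item not in df.columns:
            recoded[item] = pd.Series(np.nan, index=df.index)
            continue
        col = df[item]
        norm = col.map(lambda v: None if _is_missing(v) else normalize_label(v))
        vals = norm.map(lambda k: np.nan if k is None else table.get(k, -1.0))
        bad = vals == -1.0
        if bad.any():
            first = col[bad].iloc[0]
            raise IllegalResponseError(item, first)
        recoded[item] = vals.astype(float)
    rec = pd.DataFrame(recoded, index=df.index)
    out = {}
    for scale, items in SF36_SCALES.items():
        block = rec[list(items)]
        answered = block.notna().sum(axis=1)
        mean = block.mean(axis=1)
        mean[len(items) - answered > len(items) / 2] = np.nan
        out[scale] = mean
    return pd.DataFrame(out, index=df.index)
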