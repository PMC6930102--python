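"""EQ-5D-3L health profiles and their conversion to index utilities.

The EQ-5D-3L describes health on five dimensions — mobility, self-care,
usual activities, pain/discomfort, anxiety/depression — each at one of
three ordinal levels (1 = no problems, 3 = worst).  A complete profile
(one of 3^5 = 243 states) is converted to a single utility, anchored at
1.0 for full health, via a country-specific value set (tariff).

Value sets are data, not code: a JSON file either tabulates all 243
states explicitly or gives an additive decrement model (constant applied
on any departure from full health, per-dimension level decrements, and an
optional extra term when any dimension is at level 3).  The packaged
default is the UK time-trade-off tariff; others plug in via
:meth:`UtilityValueSet.from_json`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .sf36 import IllegalResponseError, normalize_label

__all__ = [
    "DIMENSIONS",
    "LEVEL_LABELS",
    "UtilityValueSet",
    "parse_level",
    "eq5d_utility",
    "eq5d_utility_frame",
]

logger = logging.getLogger(__name__)

DIMENSIONS: tuple[str, ...] = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)

# Three ordered levels per dimension; each level accepts several label
# aliases (3L questionnaire wording and common shorthand) plus codes 1-3.
LEVEL_LABELS: dict[str, tuple[tuple[str, ...], ...]] = {
    "mobility": (
        ("no problems", "no problems in walking about"),
        ("some problems", "some problems in walking about"),
        ("confined to bed",),
    ),
    "self_care": (
        ("no problems", "no problems with self-care"),
        ("some problems", "some problems washing or dressing myself"),
        (
            "inability to wash or dress himself/herself",
            "unable to wash or dress myself",
            "unable to wash or dress",
        ),
    ),
    "usual_activities": (
        ("no problems", "no problems with performing my usual activities"),
        ("some problems", "some problems with performing my usual activities"),
        (
            "inability to perform usual activities",
            "unable to perform my usual activities",
            "unable to perform usual activities",
        ),
    ),
    "pain_discomfort": (
        ("no pain", "no pain or discomfort"),
        ("moderate pain", "moderate pain or discomfort"),
        ("extreme pain", "extreme pain or discomfort"),
    ),
    "anxiety_depression": (
        ("no anxiety", "not anxious or depressed"),
        ("moderate anxiety", "moderately anxious or depressed"),
        ("extreme anxiety", "extremely anxious or depressed"),
    ),
}

_LOOKUP: dict[str, dict[str, int]] = {
    dim: {alias: lvl + 1 for lvl, aliases in enumerate(levels) for alias in aliases}
    for dim, levels in LEVEL_LABELS.items()
}


def _is_missing(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def parse_level(dim: str, value: object) -> int | None:
    """Ordinal level 1-3 of a dimension response; ``None`` if missing.

    Accepts the 3L label wordings (case-insensitively) and the numeric
    codes 1/2/3.
    """
    if _is_missing(value):
        return None
    if isinstance(value, (int, np.integer)) or (
        isinstance(value, float) and float(value).is_integer()
    ):
        lvl = int(value)
        if lvl in (1, 2, 3):
            return lvl
        raise IllegalResponseError(dim, value)
    key = normalize_label(value)
    if key in ("1", "2", "3"):
        return int(key)
    lvl = _LOOKUP[dim].get(key)
    if lvl is None:
        raise IllegalResponseError(dim, value)
    return lvl


def _state_key(levels: tuple[int, ...]) -> str:
    return "".join(str(l) for l in levels)


@dataclass(frozen=True)
class UtilityValueSet:
    """A named tariff mapping every complete 3L profile to a utility.

    ``values`` is keyed by 5-digit state strings (``"11111"`` .. ``"33333"``,
    dimension order mobility / self-care / usual activities /
    pain-discomfort / anxiety-depression).
    """

    name: str
    values: Mapping[str, float] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.values) != 243:
            raise ValueError(
                f"value set {self.name!r} covers {len(self.values)} of 243 states"
            )
        for state, u in self.values.items():
            if not np.isfinite(u) or u > 1.0 + 1e-12:
                raise ValueError(f"state {state}: utility {u!r} not finite and <= 1")
        if abs(self.values["11111"] - 1.0) > 1e-12:
            raise ValueError("full-health state 11111 must map to exactly 1.0")

    def lookup(self, levels: tuple[int, int, int, int, int]) -> float:
        return float(self.values[_state_key(levels)])

    @property
    def minimum(self) -> float:
        return float(min(self.values.values()))

    @classmethod
    def from_model(
        cls,
        name: str,
        constant: float,
        n3: float,
        decrements: Mapping[str, tuple[float, float]],
    ) -> "UtilityValueSet":
        """Expand an additive decrement model to the full 243-state table."""
        missing = set(DIMENSIONS) - set(decrements)
        if missing:
            raise ValueError(f"decrements missing dimensions: {sorted(missing)}")
        table: dict[str, float] = {}
        for levels in product((1, 2, 3), repeat=5):
            u = 1.0
            if any(l > 1 for l in levels):
                u -= constant
            if any(l == 3 for l in levels):
                u -= n3
            for dim, l in zip(DIMENSIONS, levels):
                if l > 1:
                    u -= float(decrements[dim][l - 2])
            table[_state_key(levels)] = u
        return cls(name=name, values=table)

    @classmethod
    def from_json(cls, source: str | Path) -> "UtilityValueSet":
        """Load a tariff from a JSON file path or a packaged tariff name."""
        path = Path(source)
        if path.suffix == ".json" and path.exists():
            payload = json.loads(path.read_text())
        else:
            ref = resources.files("frailtykit.data") / f"eq5d3l_{source}.json"
            try:
                payload = json.loads(ref.read_text())
            except FileNotFoundError:
                raise ValueError(f"unknown value set {source!r}") from None
        name = payload.get("name", str(source))
        if "states" in payload:
            return cls(name=name, values={k: float(v) for k, v in payload["states"].items()})
        m = payload["model"]
        return cls.from_model(
            name,
            constant=float(m["constant"]),
            n3=float(m.get("n3", 0.0)),
            decrements={d: tuple(v) for d, v in m["decrements"].items()},
        )


def eq5d_utility(resp: Mapping[str, object], vs: UtilityValueSet) -> float | None:
    """Index utility of one EQ-5D-3L response under a value set.

    Utility is undefined (``None``, with a logged reason) unless all five
    dimensions are answered.
    """
    levels = []
    for dim in DIMENSIONS:
        lvl = parse_level(dim, resp.get(dim))
        if lvl is None:
            logger.info("utility undefined: dimension %r missing", dim)
            return None
        levels.append(lvl)
    return vs.lookup(tuple(levels))


def eq5d_utility_frame(df: pd.DataFrame, vs: UtilityValueSet) -> pd.Series:
    """Utility per row of a wide table with the five dimension columns.

    Rows with any missing dimension get NaN.
    """
    keys = []
    for dim in DIMENSIONS:
        col = df[dim] if dim in df.columns else pd.Series(np.nan, index=df.index)
        keys.append(col.map(lambda v, d=dim: parse_level(d, v)))
    lv = pd.DataFrame(dict(zip(DIMENSIONS, keys)), index=df.index)
    complete = lv.notna().all(axis=1)
    out = pd.Series(np.nan, index=df.index, dtype=float)
    if complete.any():
        states = lv[complete].astype(int).astype(str).agg("".join, axis=1)
        out[complete] = states.map(vs.values).astype(float)
    n_bad = int((~complete).sum())
    if n_bad:
        logger.info("utility undefined for %d rows with incomplete profiles", n_bad)
    return out
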