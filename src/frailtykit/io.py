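"""Table I/O, run configuration and the end-to-end pipeline.

Interchange format is plain CSV (UTF-8, "." decimal, missing as empty
field): one row per subject-visit, columns named by item codes (``q1``,
``q3a``, ...), EQ-5D dimensions (``mobility``, ...), comorbidity flags and
battery item ids, plus mandatory ``subject_id`` and ``age``.  Numeric
response codings are accepted through a declared code map (JSON/YAML,
``{column: {code: label}}``).

:func:`run_pipeline` orchestrates the full analysis: score questionnaires,
compute one or both frailty indices, run saturation diagnostics,
inter-index concordance, FI-versus-age trend fits and post-dose
trajectory summaries, writing CSV/JSON reports plus a run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .analytics import (
    AgeTrendFit,
    ConcordanceResult,
    concordance,
    fit_age_trend,
    summarize_trajectories,
)
from .deficits import (
    DeficitSchema,
    build_prospective_schema,
    build_retrospective_schema,
    compute_fi_frame,
    load_schema,
    map_deficits_frame,
    saturation_check,
)
from .eq5d import DIMENSIONS, UtilityValueSet, eq5d_utility_frame, parse_level
from .sf36 import SF36_ITEMS, normalize_label, recode_item, score_sf36_frame
from .synthetic import CohortSpec, simulate_cohort, simulate_postdose_trajectories

__all__ = [
    "RunConfig",
    "PipelineError",
    "PipelineResult",
    "read_questionnaire_table",
    "load_code_map",
    "resolve_schema",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("subject_id", "age")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def load_code_map(source: str | Path) -> dict[str, dict[str, str]]:
    """Load a ``{column: {code: label}}`` map from JSON or YAML."""
    payload = yaml.safe_load(Path(source).read_text())
    if not isinstance(payload, dict):
        raise ValueError(f"{source}: code map must be a mapping of columns")
    return {
        str(col): {str(code): str(label) for code, label in mapping.items()}
        for col, mapping in payload.items()
    }


def _apply_code_map(df: pd.DataFrame, code_map: Mapping[str, Mapping[str, str]]) -> pd.DataFrame:
    df = df.copy()
    for col, mapping in code_map.items():
        if col in df.columns:
            df[col] = df[col].map(
                lambda v: mapping.get(str(v).strip(), v) if v is not None and v == v else v
            )
    return df


def read_questionnaire_table(
    path: str | Path,
    code_map: Mapping[str, Mapping[str, str]] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Read and validate a wide questionnaire table.

    Returns the validated records and a per-row error report; rows with
    illegal SF-36/EQ-5D labels or an unusable age are excluded (and
    counted), not fatal.  Missing mandatory columns or an empty file are
    fatal.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=object, keep_default_na=False, na_values=[""])
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty input file") from None
    if df.empty:
        raise ValueError(f"{path}: input file has a header but no rows")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    if code_map:
        df = _apply_code_map(df, code_map)

    errors: list[dict] = []
    bad_rows: set = set()

    age = pd.to_numeric(df["age"], errors="coerce")
    for idx in df.index[age.isna()]:
        errors.append({"row": int(idx), "column": "age", "value": df.loc[idx, "age"],
                       "reason": "age missing or non-numeric"})
        bad_rows.add(idx)
    df["age"] = age

    def _check(col: str, parser) -> None:
        if col not in df.columns:
            return
        for idx, value in df[col].items():
            if value is None or value != value:
                continue
            try:
                parser(value)
            except Exception as exc:
                errors.append({"row": int(idx), "column": col, "value": value,
                               "reason": str(exc)})
                bad_rows.add(idx)

    for item in SF36_ITEMS:
        _check(item, lambda v, it=item: recode_item(it, v))
    for dim in DIMENSIONS:
        _check(dim, lambda v, d=dim: parse_level(d, v))

    if bad_rows:
        logger.warning("excluded %d malformed rows of %d", len(bad_rows), len(df))
        df = df.drop(index=sorted(bad_rows))
    if df.empty:
        raise ValueError(f"{path}: no valid rows remain after validation")
    return df.reset_index(drop=True), errors


def resolve_schema(selection: str) -> DeficitSchema:
    """A schema by name ("retrospective" / "prospective") or config path."""
    if selection == "retrospective":
        return build_retrospective_schema()
    if selection == "prospective":
        return build_prospective_schema()
    path = Path(selection)
    if path.suffix.lower() in (".yaml", ".yml", ".json") and path.exists():
        return load_schema(path)
    raise ValueError(f"unknown schema {selection!r} (not a built-in name or config file)")


class RunConfig(BaseModel):
    """Configuration of one pipeline run (defaults < YAML file < CLI flags)."""

    input: Path | None = None
    trajectories_input: Path | None = None
    simulate: CohortSpec | None = None
    schemas: tuple[str, ...] = ("retrospective", "prospective")
    value_set: str = "uk_tto"
    code_map: Path | None = None
    floor: float = Field(0.8, ge=0.0, le=1.0)
    cutoffs: tuple[float, float] = (0.08, 0.25)
    saturation_threshold: float = Field(0.8, gt=0.0, le=1.0)
    young_range: tuple[float, float] = (50, 59)
    trend_forms: tuple[str, ...] = ("linear", "exponential")
    granularity: str = "subject"
    simulate_trajectories: bool = True
    outdir: Path | None = None
    seed: int = 0
    verbosity: str = "INFO"

    @field_validator("input", "trajectories_input", "code_map")
    @classmethod
    def _exists(cls, v: Path | None) -> Path | None:
        if v is not None and not Path(v).exists():
            raise ValueError(f"file not found: {v}")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)


@dataclass
class PipelineResult:
    """In-memory bundle of everything one run produced."""

    records: pd.DataFrame
    scores: pd.DataFrame  # per-subject SF-36 scales + EQ-5D utility
    fi_tables: dict[str, pd.DataFrame]
    saturation: dict[str, pd.DataFrame]
    concordance: ConcordanceResult | None
    trend_fits: pd.DataFrame
    trajectories: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis described by ``config``.

    Deterministic given fixed inputs and seed.  Any stage failure aborts
    with the stage name and cause.  When ``outdir`` is set, per-schema FI
    tables, saturation reports, the concordance report (JSON and text),
    trend fits, the trajectory summary and a run manifest are written
    there.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    @_stage("load")
    def load() -> tuple[pd.DataFrame, list[dict]]:
        if config.input is not None:
            cm = load_code_map(config.code_map) if config.code_map else None
            return read_questionnaire_table(config.input, cm)
        spec = config.simulate or CohortSpec(seed=config.seed)
        return simulate_cohort(spec), []

    records, row_errors = load()

    @_stage("score")
    def score() -> pd.DataFrame:
        scales = score_sf36_frame(records)
        vs = UtilityValueSet.from_json(config.value_set)
        utility = eq5d_utility_frame(records, vs)
        out = pd.concat([records[["subject_id", "age"]], scales], axis=1)
        out["eq5d_utility"] = utility
        return out

    scores = score()

    @_stage("frailty")
    def frailty() -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame], dict[str, DeficitSchema]]:
        fi_tables: dict[str, pd.DataFrame] = {}
        saturation: dict[str, pd.DataFrame] = {}
        schemas: dict[str, DeficitSchema] = {}
        for selection in config.schemas:
            schema = resolve_schema(selection)
            schema = DeficitSchema(name=schema.name, items=schema.items, cutoffs=config.cutoffs)
            item_scores = map_deficits_frame(records, schema)
            fi = compute_fi_frame(item_scores, schema, floor=config.floor)
            fi.insert(0, "subject_id", records["subject_id"])
            fi.insert(1, "age", records["age"])
            fi_tables[selection] = fi
            saturation[selection] = saturation_check(
                item_scores,
                records["age"],
                young_range=config.young_range,
                threshold=config.saturation_threshold,
            )
            schemas[selection] = schema
        return fi_tables, saturation, schemas

    fi_tables, saturation, schemas = frailty()

    @_stage("concordance")
    def concord() -> ConcordanceResult | None:
        if len(config.schemas) < 2:
            return None
        a, b = config.schemas[0], config.schemas[1]
        paired = pd.DataFrame(
            {"a": fi_tables[a]["category"], "b": fi_tables[b]["category"]}
        ).dropna()
        return concordance(list(paired["a"]), list(paired["b"]))

    concordance_result = concord()

    @_stage("trend")
    def trends() -> pd.DataFrame:
        rows = []
        for selection in config.schemas:
            fi = fi_tables[selection].dropna(subset=["fi"])
            for form in config.trend_forms:
                fit = fit_age_trend(fi["age"], fi["fi"], form=form,
                                    granularity=config.granularity)
                rows.append({"schema": selection, **fit.__dict__,
                             "age_min": fit.age_range[0], "age_max": fit.age_range[1]})
        df = pd.DataFrame(rows).drop(columns=["age_range"])
        return df

    trend_fits = trends()

    @_stage("trajectories")
    def trajectories() -> pd.DataFrame | None:
        cat_source = "prospective" if "prospective" in fi_tables else config.schemas[0]
        cats = pd.Series(
            fi_tables[cat_source]["category"].to_numpy(),
            index=records["subject_id"],
        ).dropna()
        if config.trajectories_input is not None:
            daily = pd.read_csv(config.trajectories_input)
        elif config.simulate_trajectories and config.input is None:
            cohort = pd.DataFrame(
                {
                    "subject_id": records["subject_id"],
                    "category": fi_tables[cat_source]["category"].to_numpy(),
                    "pf_baseline": scores["physical_functioning"],
                    "utility_baseline": scores["eq5d_utility"],
                }
            ).dropna()
            daily = simulate_postdose_trajectories(cohort, seed=config.seed)
        else:
            return None
        return summarize_trajectories(daily, cats)

    trajectory_summary = trajectories()

    manifest = {
        "package": "frailtykit",
        "version": __version__,
        "created_at": datetime.now(timezone.utc).isoformat(),
        "config": json.loads(config.model_dump_json()),
        "n_subjects": int(len(records)),
        "n_row_errors": len(row_errors),
        "schemas": {sel: {"name": s.name, "n_items": s.n_items} for sel, s in schemas.items()},
    }

    result = PipelineResult(
        records=records,
        scores=scores,
        fi_tables=fi_tables,
        saturation=saturation,
        concordance=concordance_result,
        trend_fits=trend_fits,
        trajectories=trajectory_summary,
        manifest=manifest,
    )
    if outdir:
        _write_outputs(result, outdir, row_errors)
    return result


def _write_outputs(result: PipelineResult, outdir: Path, row_errors: list[dict]) -> None:
    for selection, fi in result.fi_tables.items():
        fi.to_csv(outdir / f"fi_{selection}.csv", index=False)
    for selection, sat in result.saturation.items():
        sat.to_csv(outdir / f"saturation_{selection}.csv", index_label="item")
    result.scores.to_csv(outdir / "scores.csv", index=False)
    result.trend_fits.to_csv(outdir / "trend_fits.csv", index=False)
    if result.trajectories is not None:
        result.trajectories.to_csv(outdir / "trajectories.csv", index=False)
    if result.concordance is not None:
        payload = result.concordance.as_dict()
        (outdir / "concordance.json").write_text(json.dumps(payload, indent=2))
        ct = result.concordance.crosstab
        lines = [
            "Concordance of frailty categorisations",
            str(ct.to_frame()),
            f"agreement: {payload['agreement_count']}/{payload['n']} "
            f"({payload['agreement_percent']:.1f}%)",
            f"Kendall tau-b: {payload['tau_b']:.4f} (p = {payload['p_value']:.3g})"
            if payload["tau_b"] is not None
            else f"Kendall tau-b: undefined ({payload['note']})",
        ]
        (outdir / "concordance.txt").write_text("\n".join(lines) + "\n")
    if row_errors:
        (outdir / "row_errors.json").write_text(json.dumps(row_errors, indent=2))
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
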