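import numpy as np
import pytest

from frailtykit import (
    CohortSpec,
    UtilityValueSet,
    build_prospective_schema,
    build_retrospective_schema,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def retro_schema():
    return build_retrospective_schema()


@pytest.fixture(scope="session")
def prosp_schema():
    return build_prospective_schema()


@pytest.fixture(scope="session")
def uk_value_set():
    return UtilityValueSet.from_json("uk_tto")


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 150-subject synthetic cohort."""
    return simulate_cohort(CohortSpec(n_per_stratum=(50, 50, 50), seed=123))


def best_responses(schema) -> dict:
    """A record answering every schema source at its zero-deficit level."""
    rec = {}
    for item in schema.items:
        if item.source_type == "eq5d":
            rec[item.column] = 1
        elif item.source_type == "comorbidity":
            rec[item.column] = "No"
        else:
            rec[item.column] = next(k for k, v in item.mapping.items() if v == 0.0)
    return rec


def worst_responses(schema) -> dict:
    """A record answering every schema source at its full-deficit level."""
    rec = {}
    for item in schema.items:
        if item.source_type == "eq5d":
            rec[item.column] = 3
        elif item.source_type == "comorbidity":
            rec[item.column] = "Yes"
        else:
            rec[item.column] = next(k for k, v in item.mapping.items() if v == 1.0)
    return rec
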