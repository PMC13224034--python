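"""Shared fixtures: tiny cohort tables and small synthetic datasets.

All fixtures are generated programmatically; nothing is read from disk
except files the tests themselves write to tmp_path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dauplift.harmonize import (
    CohortSchema,
    CohortTable,
    derive_proxies,
    medical_rules,
    psychiatric_rules,
    quarantine_rules,
)
from dauplift.simulate import SyntheticSpec, generate_cohorts


@pytest.fixture
def medical_schema() -> CohortSchema:
    return CohortSchema(
        features=["age", "mbi_ex", "cesd"],
        treatment_source="mbi_ex",
        outcome_source="cesd",
        gender="sex",
        education="education_years",
        gender_map={"1": 0, "2": 1},
    )


@pytest.fixture
def medical_table(medical_schema) -> CohortTable:
    rng = np.random.default_rng(11)
    n = 40
    df = pd.DataFrame({
        "age": rng.integers(18, 30, n),
        "sex": rng.choice([1, 2], n),
        "mbi_ex": rng.integers(0, 30, n),
        "cesd": rng.integers(0, 40, n),
        "education_years": rng.integers(12, 18, n),
    })
    table = CohortTable(df=df, cohort_id=0, name="medical", schema=medical_schema)
    return derive_proxies(table, medical_rules())


@pytest.fixture
def quarantine_table() -> CohortTable:
    rng = np.random.default_rng(12)
    n = 35
    schema = CohortSchema(
        features=["age", "frustration", "growing_stress"],
        treatment_source="growing_stress",
        outcome_source="coping_struggles",
        gender="gender",
        gender_map={"male": 0, "female": 1},
        categorical=["growing_stress"],
    )
    df = pd.DataFrame({
        "age": rng.integers(18, 60, n),
        "gender": rng.choice(["male", "female"], n),
        "frustration": rng.integers(0, 10, n),
        "growing_stress": rng.choice(["yes", "maybe", "no"], n),
        "coping_struggles": rng.choice(["yes", "no"], n),
    })
    table = CohortTable(df=df, cohort_id=1, name="quarantine", schema=schema)
    return derive_proxies(table, quarantine_rules())


@pytest.fixture
def psychiatric_table() -> CohortTable:
    rng = np.random.default_rng(13)
    n = 45
    schema = CohortSchema(
        features=["age", "iq", "main_disorder"],
        treatment_source="main_disorder",
        outcome_source="main_disorder",
        gender="sex",
        education="education_years",
        gender_map={"m": 0, "f": 1},
        categorical=["main_disorder"],
    )
    df = pd.DataFrame({
        "age": rng.integers(18, 65, n),
        "sex": rng.choice(["m", "f"], n),
        "iq": rng.normal(100, 15, n).round(1),
        "education_years": rng.integers(9, 18, n),
        "main_disorder": rng.choice(
            ["anxiety disorder", "mood disorder", "healthy control"], n),
    })
    table = CohortTable(df=df, cohort_id=2, name="psychiatric", schema=schema)
    return derive_proxies(table, psychiatric_rules())


@pytest.fixture(scope="session")
def small_cohort():
    """Three small synthetic domains with a strong-ish effect; session-scoped
    because several training tests reuse it read-only."""
    spec = SyntheticSpec(n_per_domain=(150, 150, 150), d=8,
                         treatment_prob=0.5, effect_amplitude=1.5,
                         missing_block_fraction=0.0, seed=42)
    return generate_cohorts(spec)
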