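"""Harmonize three heterogeneous toy cohorts into one design matrix.

Builds three small cohort tables with different instruments (a medical-style
cohort with a burnout/depression questionnaire, a quarantine-style survey
with categorical stress items, and a psychiatric-style cohort with diagnosis
labels), derives binary treatment/outcome proxies per cohort, applies the
non-binary-gender exclusion, and merges everything.  Prints the unified
dimensionality and the per-domain proxy audit: a (T=1, Y=1) count of zero in
the psychiatric-style cohort would signal mutually exclusive proxies.
"""

import numpy as np
import pandas as pd

from dauplift import (
    CohortSchema, CohortTable, apply_exclusions, derive_proxies, harmonize,
    proxy_audit,
)
from dauplift.harmonize import medical_rules, psychiatric_rules, quarantine_rules

rng = np.random.default_rng(0)

medical = CohortTable(
    pd.DataFrame({
        "age": rng.integers(19, 30, 60),
        "sex": rng.choice([1, 2, 3], 60, p=[0.45, 0.5, 0.05]),
        "mbi_ex": rng.integers(0, 30, 60),
        "cesd": rng.integers(0, 40, 60),
        "education_years": rng.integers(12, 18, 60),
    }),
    cohort_id=0, name="medical",
    schema=CohortSchema(features=["age", "mbi_ex", "cesd"],
                        treatment_source="mbi_ex", outcome_source="cesd",
                        gender="sex", education="education_years",
                        gender_map={"1": 0, "2": 1}),
)
quarantine = CohortTable(
    pd.DataFrame({
        "age": rng.integers(18, 65, 50),
        "gender": rng.choice(["male", "female"], 50),
        "frustration": rng.integers(0, 10, 50),
        "growing_stress": rng.choice(["yes", "maybe", "no"], 50),
        "coping_struggles": rng.choice(["yes", "no"], 50),
    }),
    cohort_id=1, name="quarantine",
    schema=CohortSchema(features=["age", "frustration", "growing_stress"],
                        treatment_source="growing_stress",
                        outcome_source="coping_struggles",
                        gender="gender", gender_map={"male": 0, "female": 1},
                        categorical=["growing_stress"]),
)
psychiatric = CohortTable(
    pd.DataFrame({
        "age": rng.integers(18, 70, 70),
        "sex": rng.choice(["m", "f"], 70),
        "iq": rng.normal(100, 15, 70).round(1),
        "education_years": rng.integers(9, 18, 70),
        "main_disorder": rng.choice(
            ["anxiety disorder", "mood disorder", "healthy control"], 70),
    }),
    cohort_id=2, name="psychiatric",
    schema=CohortSchema(features=["age", "iq", "main_disorder"],
                        treatment_source="main_disorder",
                        outcome_source="main_disorder",
                        gender="sex", education="education_years",
                        gender_map={"m": 0, "f": 1},
                        categorical=["main_disorder"]),
)

medical = apply_exclusions(derive_proxies(medical, medical_rules()))
quarantine = derive_proxies(quarantine, quarantine_rules())
psychiatric = derive_proxies(psychiatric, psychiatric_rules())

# leakage-safe default: fit all transforms on the training domains only
data = harmonize([medical, quarantine, psychiatric], fit_on={0, 1})

print(f"harmonized: n = {data.n} rows, d = {data.d} unified features")
print(f"non-binary rows excluded from medical: {60 - (data.D == 0).sum()}")
for dom, name in [(0, "medical"), (1, "quarantine"), (2, "psychiatric")]:
    audit = proxy_audit(data, dom)
    print(f"{name:12s} Prev(T)={audit.prev_t:.3f} Prev(Y)={audit.prev_y:.3f} "
          f"(T=1,Y=1) cell={audit.counts[1, 1]} "
          f"mutually_exclusive={audit.mutually_exclusive}")
# In the psychiatric-style cohort T (anxiety dx) and Y (mood dx) come from
# the same diagnosis column, so their joint cell is structurally zero.
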