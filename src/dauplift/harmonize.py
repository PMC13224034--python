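"""Cohort harmonization: proxy derivation, exclusions, and a unified design matrix.

Heterogeneous per-cohort tables (different instruments, different columns)
are merged into one design matrix X with binary treatment/outcome proxies
T and Y, integer domain IDs D, and binary protected-attribute masks G
(gender) and E (education, binned at >= 12 years).

Columns absent in a cohort are *missing-by-design*: they are imputed with
the median (numeric) or mode (categorical) computed over the fit domains
only, then categorical columns are one-hot encoded with categories learned
on the fit rows, then numeric columns are z-scored with fit statistics.
Fitting on the training domains only is the leakage-safe default; passing
all domains in ``fit_on`` reproduces pooled preprocessing.

A 2x2 proxy audit (cross-tabulation of T and Y with conditional
probabilities) is provided as the routine structural check that treatment
and outcome proxies are not mutually exclusive categories of one variable.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "CohortSchema",
    "CohortTable",
    "HarmonizedDataset",
    "ProxyAudit",
    "QuantileThreshold",
    "ValueThreshold",
    "ResponseMap",
    "CategoryMembership",
    "ProxyRules",
    "load_cohort_table",
    "derive_proxies",
    "apply_exclusions",
    "Harmonizer",
    "harmonize",
    "proxy_audit",
]

#: Domain IDs by study population.
MEDICAL, QUARANTINE, PSYCHIATRIC = 0, 1, 2

#: Gender code for non-binary respondents in the medical cohort's sex column.
NONBINARY_CODE = 3

#: Education bin threshold (years); E = 1 iff education >= this.
EDUCATION_BIN_YEARS = 12.0


class SchemaError(ValueError):
    """A cohort table does not match its declared schema."""


@dataclass
class CohortSchema:
    """Column roles for one cohort.

    ``features`` lists predictor columns; proxy-source columns may appear in
    ``features`` too (the psychiatric-style diagnostic labels do by default,
    which is what produces the leakage failure mode).  ``gender_map`` maps
    raw gender codes to {0, 1}; ``categorical`` forces columns to be treated
    as categorical even if numerically coded.
    """

    features: list[str] = field(default_factory=list)
    treatment_source: str | None = None
    outcome_source: str | None = None
    gender: str | None = None
    education: str | None = None
    gender_map: dict | None = None
    categorical: list[str] = field(default_factory=list)
    id_column: str | None = None

    def mandatory_columns(self) -> list[str]:
        cols = list(self.features)
        for c in (self.treatment_source, self.outcome_source, self.gender, self.education):
            if c is not None and c not in cols:
                cols.append(c)
        return cols


@dataclass
class CohortTable:
    """One cohort's raw (or proxy-augmented) rows plus its domain label."""

    df: pd.DataFrame
    cohort_id: int
    name: str = ""
    schema: CohortSchema | None = None

    def __post_init__(self) -> None:
        if len(self.df) == 0:
            raise ValueError(f"cohort table {self.name!r} has no rows")
        if self.schema is not None and self.schema.id_column is not None:
            ids = self.df[self.schema.id_column]
            if ids.duplicated().any():
                raise ValueError(f"duplicate participant identifiers in {self.name!r}")

    @property
    def n(self) -> int:
        return len(self.df)


def load_cohort_table(
    path: str | Path,
    cohort_id: int,
    schema: CohortSchema,
    name: str | None = None,
) -> CohortTable:
    """Read a delimited text file (CSV, or TSV for .tsv/.txt extensions) into a
    CohortTable.  Column names are lowercased; mandatory schema columns must
    be present."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty input file: {path}") from exc
    if len(df) == 0:
        raise ValueError(f"input file has a header but no rows: {path}")
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in schema.mandatory_columns():
        if col not in df.columns:
            raise SchemaError(f"cohort file {path.name} is missing mandatory column {col!r}")
    return CohortTable(df=df, cohort_id=int(cohort_id), name=name or path.stem, schema=schema)


# ------------------------------------------------------------- proxy rules


@dataclass
class QuantileThreshold:
    """1 iff value is at or above the empirical q-quantile of the column
    (linear-interpolation quantile; ties at the threshold map to 1)."""

    column: str
    q: float = 0.75

    def apply(self, df: pd.DataFrame) -> np.ndarray:
        x = pd.to_numeric(df[self.column], errors="raise").to_numpy(float)
        cut = np.quantile(x, self.q)  # linear interpolation
        return (x >= cut).astype(int)


@dataclass
class ValueThreshold:
    """1 iff value >= cutoff."""

    column: str
    cutoff: float

    def apply(self, df: pd.DataFrame) -> np.ndarray:
        x = pd.to_numeric(df[self.column], errors="raise").to_numpy(float)
        return (x >= self.cutoff).astype(int)


@dataclass
class ResponseMap:
    """Map categorical response levels to {0, 1}; unknown levels raise."""

    column: str
    mapping: dict

    def apply(self, df: pd.DataFrame) -> np.ndarray:
        values = df[self.column].astype(str).str.strip().str.lower()
        mapping = {str(k).strip().lower(): int(v) for k, v in self.mapping.items()}
        unknown = sorted(set(values) - set(mapping))
        if unknown:
            raise ValueError(
                f"unknown response level(s) in column {self.column!r}: {unknown}")
        return values.map(mapping).to_numpy(int)


@dataclass
class CategoryMembership:
    """1 iff the value belongs to the given category set."""

    column: str
    categories: frozenset

    def __post_init__(self) -> None:
        self.categories = frozenset(str(c).strip().lower() for c in self.categories)

    def apply(self, df: pd.DataFrame) -> np.ndarray:
        values = df[self.column].astype(str).str.strip().str.lower()
        return values.isin(self.categories).to_numpy().astype(int)


@dataclass
class ProxyRules:
    treatment: object
    outcome: object


def medical_rules(exhaustion_col: str = "mbi_ex", depression_col: str = "cesd") -> ProxyRules:
    """Burnout-exhaustion >= P75 as T; depression score >= 10 as Y."""
    return ProxyRules(
        treatment=QuantileThreshold(exhaustion_col, 0.75),
        outcome=ValueThreshold(depression_col, 10.0),
    )


def quarantine_rules(stress_col: str = "growing_stress",
                     coping_col: str = "coping_struggles") -> ProxyRules:
    """Growing stress (yes/maybe -> 1, no -> 0) as T; coping struggles (yes) as Y."""
    return ProxyRules(
        treatment=ResponseMap(stress_col, {"yes": 1, "maybe": 1, "no": 0}),
        outcome=ResponseMap(coping_col, {"yes": 1, "no": 0}),
    )


def psychiatric_rules(diagnosis_col: str = "main_disorder",
                      anxiety_categories=("anxiety disorder",),
                      mood_categories=("mood disorder",)) -> ProxyRules:
    """Anxiety-spectrum diagnosis as T; mood-disorder/MDD diagnosis as Y."""
    return ProxyRules(
        treatment=CategoryMembership(diagnosis_col, frozenset(anxiety_categories)),
        outcome=CategoryMembership(diagnosis_col, frozenset(mood_categories)),
    )


def derive_proxies(table: CohortTable, rules: ProxyRules) -> CohortTable:
    """Return a copy of the table with binary ``t`` and ``y`` proxy columns."""
    df = table.df.copy()
    df["t"] = rules.treatment.apply(df)
    df["y"] = rules.outcome.apply(df)
    return CohortTable(df=df, cohort_id=table.cohort_id, name=table.name, schema=table.schema)


def apply_exclusions(table: CohortTable, nonbinary_code: int = NONBINARY_CODE) -> CohortTable:
    """Drop non-binary gender codes from the medical cohort (required for the
    binary-gender fairness mask).  The rule is scoped to cohort_id == 0; other
    cohorts pass through unchanged.  Never changes the column set."""
    if table.cohort_id != MEDICAL or table.schema is None or table.schema.gender is None:
        return table
    gender = pd.to_numeric(table.df[table.schema.gender], errors="coerce")
    keep = gender != nonbinary_code
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("excluded %d non-binary rows from cohort %r", n_excluded, table.name)
    df = table.df.loc[keep].reset_index(drop=True)
    return CohortTable(df=df, cohort_id=table.cohort_id, name=table.name, schema=table.schema)


# ----------------------------------------------------------- harmonization


@dataclass
class HarmonizedDataset:
    """Unified design matrix with proxies, domain IDs, and protected masks."""

    X: np.ndarray
    T: np.ndarray
    Y: np.ndarray
    D: np.ndarray
    G: np.ndarray
    E: np.ndarray
    column_names: list[str]
    feature_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        for name in ("T", "Y", "D", "G", "E"):
            setattr(self, name, np.asarray(getattr(self, name), int))
        n = self.X.shape[0]
        for name in ("T", "Y", "D", "G", "E"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have length {n}")
        for name in ("T", "Y", "G", "E"):
            vals = np.unique(getattr(self, name))
            if not np.all(np.isin(vals, [0, 1])):
                raise ValueError(f"{name} must be binary, found values {vals}")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values after harmonization")
        if self.X.shape[1] != len(self.column_names):
            raise ValueError("column_names length must match X width")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def domains(self) -> np.ndarray:
        return np.unique(self.D)

    def subset(self, mask: np.ndarray) -> "HarmonizedDataset":
        mask = np.asarray(mask)
        return HarmonizedDataset(
            X=self.X[mask], T=self.T[mask], Y=self.Y[mask], D=self.D[mask],
            G=self.G[mask], E=self.E[mask],
            column_names=list(self.column_names), feature_meta=dict(self.feature_meta),
        )

    def domain_subset(self, domain: int) -> "HarmonizedDataset":
        return self.subset(self.D == domain)

    def drop_columns(self, names: list[str]) -> "HarmonizedDataset":
        keep = [i for i, c in enumerate(self.column_names) if c not in set(names)]
        return HarmonizedDataset(
            X=self.X[:, keep], T=self.T, Y=self.Y, D=self.D, G=self.G, E=self.E,
            column_names=[self.column_names[i] for i in keep],
            feature_meta={k: v for k, v in self.feature_meta.items()},
        )

    def to_csv(self, path: str | Path) -> None:
        """Write rows as CSV plus a JSON sidecar with column metadata."""
        path = Path(path)
        df = pd.DataFrame(self.X, columns=self.column_names)
        for name, vec in (("t", self.T), ("y", self.Y), ("d", self.D),
                          ("g", self.G), ("e", self.E)):
            df[name] = vec
        df.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(
            {"column_names": self.column_names, "feature_meta": self.feature_meta},
            indent=2, default=str))

    @classmethod
    def from_csv(cls, path: str | Path) -> "HarmonizedDataset":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        cols = meta.get("column_names",
                        [c for c in df.columns if c not in ("t", "y", "d", "g", "e")])
        return cls(X=df[cols].to_numpy(float), T=df["t"], Y=df["y"], D=df["d"],
                   G=df["g"], E=df["e"], column_names=list(cols),
                   feature_meta=meta.get("feature_meta", {}))


class Harmonizer:
    """Fit imputation/encoding/scaling statistics on a subset of domains and
    apply them to all rows.  Statistics depend only on ``fit_on`` rows."""

    def __init__(self, drop_proxy_sources: bool = False):
        self.drop_proxy_sources = drop_proxy_sources
        self.fitted_ = False

    # -- assembling the pooled raw frame ------------------------------------

    def _assemble(self, tables: list[CohortTable]) -> tuple[pd.DataFrame, dict]:
        frames = []
        availability: dict[str, list[int]] = {}
        feature_cols: list[str] = []
        for tab in tables:
            if tab.schema is None:
                raise SchemaError(f"cohort {tab.name!r} has no schema")
            cols = list(tab.schema.features)
            if self.drop_proxy_sources:
                drop = {tab.schema.treatment_source, tab.schema.outcome_source}
                cols = [c for c in cols if c not in drop]
            for c in cols:
                if c not in feature_cols:
                    feature_cols.append(c)
                availability.setdefault(c, []).append(tab.cohort_id)
            sub = tab.df[cols].copy()
            for aux in ("t", "y"):
                if aux not in tab.df.columns:
                    raise SchemaError(
                        f"cohort {tab.name!r} lacks proxy column {aux!r}; "
                        "run derive_proxies first")
                sub[f"__{aux}"] = tab.df[aux].to_numpy()
            sub["__d"] = tab.cohort_id
            # gender mask
            if tab.schema.gender is not None:
                raw = tab.df[tab.schema.gender]
                if tab.schema.gender_map is not None:
                    gm = {str(k).strip().lower(): int(v)
                          for k, v in tab.schema.gender_map.items()}
                    g = raw.astype(str).str.strip().str.lower().map(gm)
                    if g.isna().any():
                        bad = sorted(set(raw[g.isna()].astype(str)))
                        raise SchemaError(
                            f"unmapped gender values in cohort {tab.name!r}: {bad}")
                    sub["__g"] = g.to_numpy(int)
                else:
                    sub["__g"] = pd.to_numeric(raw).to_numpy(int)
            else:
                sub["__g"] = 0
            sub["__edu"] = (pd.to_numeric(tab.df[tab.schema.education], errors="coerce")
                            if tab.schema.education is not None else np.nan)
            frames.append(sub)
        pooled = pd.concat(frames, axis=0, ignore_index=True)
        return pooled, {"availability": availability, "feature_cols": feature_cols}

    def fit(self, tables: list[CohortTable], fit_on: set[int]) -> "Harmonizer":
        if not tables:
            raise ValueError("harmonize needs at least one cohort table")
        fit_on = set(int(v) for v in fit_on)
        supplied = {tab.cohort_id for tab in tables}
        if not fit_on or not fit_on.issubset(supplied):
            raise ValueError(f"fit_on {fit_on} must be a non-empty subset of {supplied}")
        pooled, meta = self._assemble(tables)
        fit_rows = pooled["__d"].isin(fit_on)
        self.fit_on_ = fit_on
        self.feature_cols_ = meta["feature_cols"]
        self.availability_ = meta["availability"]
        self.numeric_cols_ = []
        self.categorical_cols_ = []
        forced_cat = set()
        for tab in tables:
            forced_cat.update(tab.schema.categorical)
        for c in self.feature_cols_:
            col = pooled[c]
            if c in forced_cat:
                self.categorical_cols_.append(c)
            elif pd.api.types.is_numeric_dtype(col):
                self.numeric_cols_.append(c)
            else:
                parsed = pd.to_numeric(col, errors="coerce")
                if col.notna().any() and parsed.notna().sum() == col.notna().sum():
                    self.numeric_cols_.append(c)
                else:
                    self.categorical_cols_.append(c)
        self.medians_ = {}
        self.means_ = {}
        self.stds_ = {}
        for c in self.numeric_cols_:
            x = pd.to_numeric(pooled.loc[fit_rows, c], errors="coerce")
            med = float(x.median()) if x.notna().any() else 0.0
            self.medians_[c] = med
            filled = x.fillna(med)
            self.means_[c] = float(filled.mean())
            sd = float(filled.std(ddof=0))
            if sd == 0.0:
                warnings.warn(f"zero-variance column {c!r}: passed through centered only")
            self.stds_[c] = sd
        self.modes_ = {}
        self.categories_ = {}
        for c in self.categorical_cols_:
            x = pooled.loc[fit_rows, c].astype(str).str.strip().str.lower()
            x = x.where(~pooled.loc[fit_rows, c].isna(), other=np.nan).dropna()
            mode = x.mode().iloc[0] if len(x) else "missing"
            self.modes_[c] = str(mode)
            self.categories_[c] = sorted(x.unique()) if len(x) else [str(mode)]
        edu = pooled.loc[fit_rows, "__edu"]
        self.education_median_ = float(edu.median()) if edu.notna().any() else np.nan
        self.fitted_ = True
        return self

    def transform(self, tables: list[CohortTable]) -> HarmonizedDataset:
        if not self.fitted_:
            raise RuntimeError("Harmonizer.transform called before fit")
        pooled, _ = self._assemble(tables)
        blocks = []
        names: list[str] = []
        feature_meta: dict[str, dict] = {}
        for c in self.feature_cols_:
            present_in = self.availability_.get(c, [])
            missing_in = sorted({tab.cohort_id for tab in tables} - set(present_in))
            if c in self.numeric_cols_:
                x = pd.to_numeric(pooled.get(c), errors="coerce").to_numpy(float)
                imputed = np.isnan(x)
                x = np.where(imputed, self.medians_[c], x)
                sd = self.stds_[c]
                x = (x - self.means_[c]) / sd if sd > 0 else x - self.means_[c]
                blocks.append(x[:, None])
                names.append(c)
                feature_meta[c] = {
                    "kind": "numeric", "source_cohorts": present_in,
                    "missing_by_design_in": missing_in,
                    "n_imputed": int(imputed.sum()),
                }
            else:
                raw = pooled.get(c)
                vals = raw.astype(str).str.strip().str.lower()
                vals = vals.where(~raw.isna(), other=self.modes_[c])
                cats = self.categories_[c]
                seen = vals.isin(cats)
                if not seen.all():
                    unseen = sorted(set(vals[~seen]))
                    warnings.warn(
                        f"categories unseen in fit domains for {c!r}: {unseen}; "
                        "one-hot rows are all-zero")
                onehot = np.zeros((len(vals), len(cats)))
                for j, cat in enumerate(cats):
                    onehot[:, j] = (vals == cat).to_numpy(float)
                blocks.append(onehot)
                group = [f"{c}={cat}" for cat in cats]
                names.extend(group)
                for col_name in group:
                    feature_meta[col_name] = {
                        "kind": "onehot", "onehot_group": c,
                        "source_cohorts": present_in,
                        "missing_by_design_in": missing_in,
                    }
        X = np.hstack(blocks) if blocks else np.zeros((len(pooled), 0))
        edu = pooled["__edu"].to_numpy(float)
        edu_imputed = np.isnan(edu)
        if np.isnan(self.education_median_):
            edu_filled = np.zeros_like(edu)
        else:
            edu_filled = np.where(edu_imputed, self.education_median_, edu)
        E = (edu_filled >= EDUCATION_BIN_YEARS).astype(int)
        feature_meta["__education_bin"] = {
            "kind": "mask", "threshold_years": EDUCATION_BIN_YEARS,
            "n_imputed": int(edu_imputed.sum()),
            "unreliable": bool(edu_imputed.any()),
        }
        return HarmonizedDataset(
            X=X,
            T=pooled["__t"].to_numpy(int),
            Y=pooled["__y"].to_numpy(int),
            D=pooled["__d"].to_numpy(int),
            G=pooled["__g"].to_numpy(int),
            E=E,
            column_names=names,
            feature_meta=feature_meta,
        )

    def fit_transform(self, tables: list[CohortTable], fit_on: set[int]) -> HarmonizedDataset:
        return self.fit(tables, fit_on).transform(tables)


def harmonize(
    tables: list[CohortTable],
    fit_on: set[int] | None = None,
    drop_proxy_sources: bool = False,
) -> HarmonizedDataset:
    """Merge cohort tables into one HarmonizedDataset.

    ``fit_on`` selects the domains whose rows define all imputation, encoding
    and scaling statistics (default: every supplied domain, i.e. pooled
    preprocessing).  Pass the training domains only for a leakage-safe
    transform in transfer experiments."""
    if fit_on is None:
        fit_on = {tab.cohort_id for tab in tables}
    return Harmonizer(drop_proxy_sources=drop_proxy_sources).fit_transform(tables, fit_on)


# ------------------------------------------------------------- proxy audit


@dataclass
class ProxyAudit:
    """2x2 cross-tabulation of (T, Y) with conditional outcome probabilities.

    ``mutually_exclusive`` is true iff the (T=1, Y=1) cell is zero while both
    the T=1 and Y=1 margins are non-empty -- the signature of treatment and
    outcome proxies drawn from mutually exclusive categories of one variable.
    Conditional probabilities on an empty margin are None (undefined), never 0.
    """

    counts: np.ndarray  # counts[t, y]
    n: int
    prev_t: float
    prev_y: float
    p_y1_given_t1: float | None
    p_y1_given_t0: float | None
    mutually_exclusive: bool
    undefined_margins: list[str] = field(default_factory=list)

    def to_dict(self, display: bool = False) -> dict:
        def r(v):
            if v is None:
                return None
            return round(float(v), 3) if display else float(v)

        return {
            "counts": np.asarray(self.counts, int).tolist(),
            "n": int(self.n),
            "prev_t": r(self.prev_t),
            "prev_y": r(self.prev_y),
            "p_y1_given_t1": r(self.p_y1_given_t1),
            "p_y1_given_t0": r(self.p_y1_given_t0),
            "mutually_exclusive": bool(self.mutually_exclusive),
            "undefined_margins": list(self.undefined_margins),
        }


def audit_from_counts(counts: np.ndarray) -> ProxyAudit:
    """Build a ProxyAudit directly from a 2x2 count table counts[t, y]."""
    counts = np.asarray(counts, dtype=int)
    if counts.shape != (2, 2) or (counts < 0).any():
        raise ValueError("counts must be a non-negative 2x2 table indexed [t, y]")
    n = int(counts.sum())
    if n == 0:
        raise ValueError("empty count table")
    n_t1 = int(counts[1].sum())
    n_t0 = int(counts[0].sum())
    n_y1 = int(counts[:, 1].sum())
    undefined = []
    if n_t1 > 0:
        p11 = counts[1, 1] / n_t1
    else:
        p11, undefined = None, undefined + ["t1"]
    if n_t0 > 0:
        p10 = counts[0, 1] / n_t0
    else:
        p10, undefined = None, undefined + ["t0"]
    return ProxyAudit(
        counts=counts, n=n,
        prev_t=n_t1 / n, prev_y=n_y1 / n,
        p_y1_given_t1=p11, p_y1_given_t0=p10,
        mutually_exclusive=bool(counts[1, 1] == 0 and n_t1 > 0 and n_y1 > 0),
        undefined_margins=undefined,
    )


def proxy_audit(data: HarmonizedDataset, domain: int) -> ProxyAudit:
    """Cross-tabulate T and Y within one domain of a harmonized dataset."""
    mask = data.D == domain
    if not mask.any():
        raise ValueError(f"domain {domain} not present in dataset")
    t, y = data.T[mask], data.Y[mask]
    counts = np.zeros((2, 2), dtype=int)
    for tv in (0, 1):
        for yv in (0, 1):
            counts[tv, yv] = int(np.sum((t == tv) & (y == yv)))
    return audit_from_counts(counts)
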