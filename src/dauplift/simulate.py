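"""Synthetic multi-domain cohorts with a known treatment-effect surface.

The generator emulates the structure of the three-cohort study setting:
three domains with shifted/rescaled Gaussian feature distributions,
missing-by-design feature blocks, per-domain treatment prevalences, and a
smooth heterogeneous injected effect with closed-form per-sample truth

    p_t(x) = sigmoid(beta . x + t * a * tanh(w . x)),
    u*(x)  = p_1(x) - p_0(x),

with beta, w drawn once per seed from a standard Gaussian and scaled to unit
norm.  Outcomes are Bernoulli(p_T); Bernoulli sampling is the only noise.
Because the truth u*(x) is known, CATE RMSE of any estimator is computable.

A separate leakage generator reproduces the structural failure mode in which
treatment and outcome proxies are mutually exclusive categories of one
diagnosis variable that is also one-hot encoded into the features: the
(T=1, Y=1) cell is empty by construction and, because the outcome category
attaches to the highest-effect individuals, a model that learned the true
effect surface on clean domains ranks Y=1 controls first and measures
negative net uplift on this domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .harmonize import HarmonizedDataset

__all__ = [
    "SyntheticSpec",
    "SemiSyntheticTruth",
    "generate_cohorts",
    "generate_leakage_cohort",
    "cate_rmse",
    "recovery_experiment",
]

#: Leakage class prevalences chosen to match the psychiatric-style audit
#: (outcome category ~0.285, treatment category ~0.171 of the cohort).
LEAK_OUTCOME_FRAC = 0.285
LEAK_TREATMENT_FRAC = 0.171


def _sigmoid(a: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(a, -60, 60)))


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator configuration.

    Defaults mirror the study conditions: three domains with the cohort sizes
    and treatment prevalences of the real populations, a moderate mean shift
    between domains, and a heterogeneous effect of amplitude 0.6 on the logit
    scale.  ``missing_block_fraction`` zeroes a per-domain block of columns
    and flags it missing-by-design, emulating instrument non-overlap.
    """

    n_per_domain: tuple[int, ...] = (881, 824, 919)
    d: int = 20
    domain_mean_shift: float = 0.3
    domain_scale: float = 1.0
    treatment_prob: float | tuple[float, ...] = (0.300, 0.689, 0.171)
    effect_amplitude: float = 0.6
    base_intercept: float = 0.0
    missing_block_fraction: float = 0.15
    treatment_confounding: float = 0.0
    leakage_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        probs = self.treatment_prob
        if np.isscalar(probs):
            probs = (float(probs),) * len(self.n_per_domain)
        probs = tuple(float(p) for p in probs)
        if len(probs) != len(self.n_per_domain):
            raise ValueError("treatment_prob must be scalar or one value per domain")
        if not all(0.0 < p < 1.0 for p in probs):
            raise ValueError("treatment probabilities must lie in (0, 1)")
        if any(n <= 0 for n in self.n_per_domain) or self.d <= 0:
            raise ValueError("n_per_domain and d must be positive")
        if not (0.0 <= self.missing_block_fraction < 1.0):
            raise ValueError("missing_block_fraction must be in [0, 1)")
        object.__setattr__(self, "treatment_prob", probs)
        object.__setattr__(self, "n_per_domain", tuple(int(n) for n in self.n_per_domain))

    @classmethod
    def well_specified(cls, seed: int = 0) -> "SyntheticSpec":
        """The benchmark configuration for effect-recovery experiments: three
        balanced domains of 300 (n = 900), d = 20, amplitude 0.6, moderate
        shift, no missing blocks, balanced treatment."""
        return cls(n_per_domain=(300, 300, 300), d=20, domain_mean_shift=0.3,
                   treatment_prob=0.5, effect_amplitude=0.6,
                   missing_block_fraction=0.0, seed=seed)


@dataclass
class SemiSyntheticTruth:
    """Per-sample ground truth of the injected effect surface."""

    u_star: np.ndarray
    p1: np.ndarray
    p0: np.ndarray
    T: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.u_star, self.p1 - self.p0):
            raise ValueError("u_star must equal p1 - p0 elementwise")


def _draw_features(spec: SyntheticSpec, rng: np.random.Generator):
    """Per-domain Gaussian features with mean shift k*shift and the domain's
    missing-by-design block zeroed; returns (X, D, missing_map)."""
    X_parts, D_parts = [], []
    missing_map: dict[int, list[int]] = {}
    n_missing = int(round(spec.missing_block_fraction * spec.d))
    for k, n_k in enumerate(spec.n_per_domain):
        Xk = rng.normal(loc=k * spec.domain_mean_shift, scale=spec.domain_scale,
                        size=(n_k, spec.d))
        if n_missing > 0:
            # contiguous block per domain, wrapping around the column range
            start = (k * n_missing) % spec.d
            cols = [(start + j) % spec.d for j in range(n_missing)]
            Xk[:, cols] = 0.0
            missing_map[k] = cols
        else:
            missing_map[k] = []
        X_parts.append(Xk)
        D_parts.append(np.full(n_k, k, dtype=int))
    return np.vstack(X_parts), np.concatenate(D_parts), missing_map


def _effect_surface(spec: SyntheticSpec, X: np.ndarray, rng: np.random.Generator):
    """beta, w ~ N(0, I) scaled to unit norm (drawn once per seed); returns
    (p1, p0, u_star) computed on the observed feature matrix."""
    beta = rng.standard_normal(spec.d)
    beta /= np.linalg.norm(beta)
    w = rng.standard_normal(spec.d)
    w /= np.linalg.norm(w)
    base = spec.base_intercept + X @ beta
    tau = spec.effect_amplitude * np.tanh(X @ w)
    p1 = _sigmoid(base + tau)
    p0 = _sigmoid(base)
    return p1, p0, p1 - p0


def generate_cohorts(spec: SyntheticSpec) -> tuple[HarmonizedDataset, SemiSyntheticTruth]:
    """Generate a fully synthetic multi-domain cohort plus its effect truth.

    T ~ Bernoulli(per-domain prevalence), independent of x unless
    ``treatment_confounding`` tilts the propensity along the base risk;
    Y ~ Bernoulli(p_T); G and E ~ Bernoulli(0.5) independently.
    Deterministic under spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    X, D, missing_map = _draw_features(spec, rng)
    p1, p0, u_star = _effect_surface(spec, X, rng)
    n = X.shape[0]
    probs = np.array([spec.treatment_prob[k] for k in D])
    if spec.treatment_confounding != 0.0:
        # optional confounded assignment: propensity tilted along the base
        # risk direction (off by default; randomized assignment otherwise)
        logit = np.log(probs / (1.0 - probs))
        probs = _sigmoid(logit + spec.treatment_confounding * (p0 - p0.mean()) * 4.0)
    T = (rng.random(n) < probs).astype(int)
    pT = np.where(T == 1, p1, p0)
    Y = (rng.random(n) < pT).astype(int)
    G = (rng.random(n) < 0.5).astype(int)
    E = (rng.random(n) < 0.5).astype(int)
    names = [f"x{j}" for j in range(spec.d)]
    meta = {f"x{j}": {"kind": "numeric",
                      "missing_by_design_in": [k for k, cols in missing_map.items()
                                               if j in cols]}
            for j in range(spec.d)}
    data = HarmonizedDataset(X=X, T=T, Y=Y, D=D, G=G, E=E,
                             column_names=names, feature_meta=meta)
    truth = SemiSyntheticTruth(u_star=u_star, p1=p1, p0=p0, T=T, Y=Y)
    return data, truth


def generate_leakage_cohort(
    spec: SyntheticSpec,
    drop_proxy_sources: bool = False,
) -> tuple[HarmonizedDataset, SemiSyntheticTruth]:
    """Generate the three-domain cohort where the *last* domain is the leakage
    cohort: a mutually exclusive categorical diagnosis defines its T (anxiety
    class) and Y (mood class) and is one-hot encoded into X for every domain
    (all-zero outside the leakage domain, mimicking missing-by-design).

    Within the leakage domain the mood class (Y = 1, T = 0) is assigned to
    the top-u* individuals and the anxiety class (T = 1, Y = 0) to the next
    band, so count(T=1, Y=1) = 0 by construction and a ranking aligned with
    the true effect surface measures negative net uplift there.  With
    ``drop_proxy_sources`` the diagnosis one-hot columns are omitted from X
    (the audit outcome is unchanged).
    """
    if not spec.leakage_mode:
        raise ValueError("generate_leakage_cohort requires spec.leakage_mode = True")
    data, truth = generate_cohorts(replace(spec, leakage_mode=False))
    leak_dom = len(spec.n_per_domain) - 1
    mask = data.D == leak_dom
    idx = np.flatnonzero(mask)
    u_leak = truth.u_star[idx]
    order = np.argsort(-u_leak, kind="stable")
    n_leak = len(idx)
    n_mood = int(round(LEAK_OUTCOME_FRAC * n_leak))
    n_anx = int(round(LEAK_TREATMENT_FRAC * n_leak))
    diagnosis = np.full(n_leak, "control", dtype=object)
    diagnosis[order[:n_mood]] = "mood"
    diagnosis[order[n_mood:n_mood + n_anx]] = "anxiety"

    T = data.T.copy()
    Y = data.Y.copy()
    T[idx] = (diagnosis == "anxiety").astype(int)
    Y[idx] = (diagnosis == "mood").astype(int)

    X = data.X
    names = list(data.column_names)
    meta = dict(data.feature_meta)
    if not drop_proxy_sources:
        cats = ["anxiety", "control", "mood"]
        onehot = np.zeros((data.n, len(cats)))
        for j, cat in enumerate(cats):
            col = np.zeros(data.n)
            col[idx] = (diagnosis == cat).astype(float)
            onehot[:, j] = col
        X = np.hstack([X, onehot])
        for cat in cats:
            names.append(f"diagnosis={cat}")
            meta[f"diagnosis={cat}"] = {
                "kind": "onehot", "onehot_group": "diagnosis",
                "missing_by_design_in": [k for k in range(leak_dom)],
                "proxy_source": True,
            }
    leaked = HarmonizedDataset(X=X, T=T, Y=Y, D=data.D, G=data.G, E=data.E,
                               column_names=names, feature_meta=meta)
    return leaked, truth


def cate_rmse(u_hat: np.ndarray, u_star: np.ndarray) -> float:
    """sqrt(mean((u_hat - u_star)^2)); errors on empty input."""
    from .evaluate import cate_rmse_score

    return cate_rmse_score(u_hat, u_star)


def recovery_experiment(
    spec: SyntheticSpec,
    method: str = "noda",
    config=None,
    seeds: tuple[int, ...] = (0,),
) -> dict:
    """LODO effect-recovery benchmark on a synthetic cohort.

    For every seed x fold, the model is trained on the other domains and its
    CATE RMSE on the held-out domain's u* is compared against two reference
    predictors: u == 0 and u == training-sample ATE (a constant).  Returns
    per-fold RMSEs, their mean, and the reference RMSEs per fold.
    """
    from .align import TrainConfig
    from .evaluate import run_lodo

    if spec.effect_amplitude == 0 and method != "noda":
        pass  # a null surface is a valid (nothing-to-recover) configuration
    if config is None:
        config = TrainConfig(method=method, epochs=60, patience=15)
    data, truth = generate_cohorts(spec)
    result = run_lodo(data, method, config, seeds=seeds, truth=truth.u_star)
    rows = []
    for rec in result.per_fold:
        hold = data.D == rec.fold
        u_star = truth.u_star[hold]
        src = ~hold
        ate = float(data.Y[src & (data.T == 1)].mean() - data.Y[src & (data.T == 0)].mean())
        rows.append({
            "seed": rec.seed,
            "fold": rec.fold,
            "rmse": rec.cate_rmse,
            "rmse_zero": cate_rmse(np.zeros_like(u_star), u_star),
            "rmse_ate": cate_rmse(np.full_like(u_star, ate), u_star),
            "auuc": rec.auuc,
        })
    mean_rmse = float(np.mean([r["rmse"] for r in rows]))
    return {"per_fold": rows, "mean_rmse": mean_rmse, "lodo": result}
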