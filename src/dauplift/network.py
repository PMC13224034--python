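"""Domain-adversarial uplift network in plain numpy.

The model estimates individual uplift u(x) = P(Y=1 | x, T=1) - P(Y=1 | x, T=0)
with a shared MLP encoder f_theta, two single-layer potential-outcome heads
h1/h0 (sigmoid), and a K-way domain discriminator g_phi attached through a
gradient-reversal layer (GRL).  The GRL is the identity on the forward pass;
during backpropagation the domain-loss gradient reaching the encoder is the
discriminator-side gradient scaled by -lambda_D, while the discriminator's own
parameters receive the unreversed gradient.  lambda_D = 0 therefore recovers a
plain two-head neural T-learner (the NoDA baseline).

All forward/backward passes are hand-written and checked against central
finite differences in the test suite.  Parameters live in a flat dict of
ndarrays so optimizers and checkpoint I/O stay trivial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EPS",
    "NetworkConfig",
    "LossBreakdown",
    "UpliftNetwork",
    "build_network",
    "uplift_loss",
    "fairness_penalty",
    "grl_forward",
    "grl_backward",
    "total_loss",
]

# Clamp for Bernoulli probabilities inside log-losses.
EPS = 1e-7


class ConfigError(ValueError):
    """Raised for invalid network or training configuration."""


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``input_dim`` is the width d of the harmonized design matrix,
    ``hidden_widths`` the encoder layer sizes (embedding dim m is the last
    entry), ``dropout`` the rate applied after the *first* hidden layer only,
    ``num_domains`` the number K of discriminator classes, and
    ``disc_extra_inputs`` widens the discriminator input beyond m (2 for the
    conditional variant that consumes [f(x), y0, y1]).
    """

    input_dim: int
    hidden_widths: tuple[int, ...] = (128, 64)
    dropout: float = 0.30
    num_domains: int = 3
    seed: int = 0
    disc_extra_inputs: int = 0

    def __post_init__(self) -> None:
        if self.input_dim <= 0:
            raise ConfigError(f"input_dim must be positive, got {self.input_dim}")
        if len(self.hidden_widths) == 0:
            raise ConfigError("hidden_widths must be non-empty")
        if any(w <= 0 for w in self.hidden_widths):
            raise ConfigError(f"hidden widths must be positive, got {self.hidden_widths}")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.num_domains < 2:
            raise ConfigError(f"num_domains must be >= 2, got {self.num_domains}")
        object.__setattr__(self, "hidden_widths", tuple(int(w) for w in self.hidden_widths))

    @property
    def embedding_dim(self) -> int:
        return self.hidden_widths[-1]

    def to_dict(self) -> dict:
        return {
            "input_dim": self.input_dim,
            "hidden_widths": list(self.hidden_widths),
            "dropout": self.dropout,
            "num_domains": self.num_domains,
            "seed": self.seed,
            "disc_extra_inputs": self.disc_extra_inputs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["hidden_widths"] = tuple(d["hidden_widths"])
        return cls(**d)


@dataclass
class LossBreakdown:
    """One logged training objective: total = l_uplift + lambda_d*l_domain + lambda_f*l_fair."""

    l_uplift: float
    l_domain: float
    l_fair: float
    lambda_d: float
    lambda_f: float
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = self.l_uplift + self.lambda_d * self.l_domain + self.lambda_f * self.l_fair


def _relu(a: np.ndarray) -> np.ndarray:
    return np.maximum(a, 0.0)


def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


def _uniform_init(rng: np.random.Generator, fan_in: int, shape: tuple) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class UpliftNetwork:
    """Parameter container plus hand-written forward/backward passes."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        self.grl_weight: float = 0.0
        rng = np.random.default_rng(config.seed)
        p: dict[str, np.ndarray] = {}
        widths = (config.input_dim, *config.hidden_widths)
        for i in range(len(config.hidden_widths)):
            fan_in = widths[i]
            p[f"enc_W{i}"] = _uniform_init(rng, fan_in, (widths[i], widths[i + 1]))
            p[f"enc_b{i}"] = _uniform_init(rng, fan_in, (widths[i + 1],))
        m = config.embedding_dim
        for head in ("h1", "h0"):
            p[f"{head}_w"] = _uniform_init(rng, m, (m,))
            p[f"{head}_b"] = _uniform_init(rng, m, (1,))
        din = m + config.disc_extra_inputs
        p["disc_W0"] = _uniform_init(rng, din, (din, m))
        p["disc_b0"] = _uniform_init(rng, din, (m,))
        p["disc_W1"] = _uniform_init(rng, m, (m, config.num_domains))
        p["disc_b1"] = _uniform_init(rng, m, (config.num_domains,))
        self.params = p

    # ------------------------------------------------------------------ encoder

    def encoder_forward(
        self,
        X: np.ndarray,
        train: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Return (embedding, cache).  Dropout (inverted scaling) is applied
        after the first hidden layer only, and only when ``train`` is true."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.config.input_dim:
            raise ValueError(
                f"expected X with {self.config.input_dim} columns, got shape {X.shape}"
            )
        cache: dict = {"X": X, "pre": [], "post": [], "mask": None}
        z = X
        for i in range(len(self.config.hidden_widths)):
            a = z @ self.params[f"enc_W{i}"] + self.params[f"enc_b{i}"]
            z = _relu(a)
            if i == 0 and train and self.config.dropout > 0.0:
                if dropout_rng is None:
                    raise ValueError("training-mode forward needs a dropout_rng")
                keep = 1.0 - self.config.dropout
                mask = (dropout_rng.random(z.shape) < keep) / keep
                z = z * mask
                cache["mask"] = mask
            cache["pre"].append(a)
            cache["post"].append(z)
        return z, cache

    def encoder_backward(self, cache: dict, d_emb: np.ndarray) -> dict[str, np.ndarray]:
        """Backprop d(loss)/d(embedding) to encoder parameter gradients."""
        grads: dict[str, np.ndarray] = {}
        dz = d_emb
        n_layers = len(self.config.hidden_widths)
        for i in reversed(range(n_layers)):
            a = cache["pre"][i]
            if i == 0 and cache["mask"] is not None:
                # dropout was applied after relu at layer 0
                da = dz * cache["mask"] * (a > 0)
            else:
                da = dz * (a > 0)
            z_prev = cache["X"] if i == 0 else cache["post"][i - 1]
            grads[f"enc_W{i}"] = z_prev.T @ da
            grads[f"enc_b{i}"] = da.sum(axis=0)
            if i > 0:
                dz = da @ self.params[f"enc_W{i}"].T
        return grads

    # -------------------------------------------------------------------- heads

    def heads_forward(self, emb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        y1 = _sigmoid(emb @ self.params["h1_w"] + self.params["h1_b"][0])
        y0 = _sigmoid(emb @ self.params["h0_w"] + self.params["h0_b"][0])
        return y1, y0

    def heads_backward(
        self, emb: np.ndarray, y1: np.ndarray, y0: np.ndarray,
        dy1: np.ndarray, dy0: np.ndarray,
    ) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Return (head parameter grads, d_embedding) for upstream losses on
        the sigmoid outputs."""
        grads: dict[str, np.ndarray] = {}
        da1 = dy1 * y1 * (1.0 - y1)
        da0 = dy0 * y0 * (1.0 - y0)
        grads["h1_w"] = emb.T @ da1
        grads["h1_b"] = np.array([da1.sum()])
        grads["h0_w"] = emb.T @ da0
        grads["h0_b"] = np.array([da0.sum()])
        d_emb = np.outer(da1, self.params["h1_w"]) + np.outer(da0, self.params["h0_w"])
        return grads, d_emb

    # ------------------------------------------------------------ discriminator

    def discriminator_forward(self, Z: np.ndarray) -> tuple[np.ndarray, dict]:
        """Z may be the embedding or [embedding, y0, y1]; returns (probs, cache)."""
        Z = np.asarray(Z, dtype=float)
        din = self.params["disc_W0"].shape[0]
        if Z.ndim != 2 or Z.shape[1] != din:
            raise ValueError(f"discriminator expects {din} inputs, got shape {Z.shape}")
        a = Z @ self.params["disc_W0"] + self.params["disc_b0"]
        h = _relu(a)
        logits = h @ self.params["disc_W1"] + self.params["disc_b1"]
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs, {"Z": Z, "a": a, "h": h, "probs": probs}

    def discriminator_backward(
        self, cache: dict, dlogits: np.ndarray
    ) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Return (discriminator grads, d_input)."""
        grads: dict[str, np.ndarray] = {}
        grads["disc_W1"] = cache["h"].T @ dlogits
        grads["disc_b1"] = dlogits.sum(axis=0)
        dh = dlogits @ self.params["disc_W1"].T
        da = dh * (cache["a"] > 0)
        grads["disc_W0"] = cache["Z"].T @ da
        grads["disc_b0"] = da.sum(axis=0)
        dZ = da @ self.params["disc_W0"].T
        return grads, dZ

    # ---------------------------------------------------------------- inference

    def forward_potential_outcomes(
        self, X: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Evaluation-mode forward (dropout off): (y_hat_1, y_hat_0, embedding)."""
        emb, _ = self.encoder_forward(X, train=False)
        y1, y0 = self.heads_forward(emb)
        return y1, y0, emb

    def predict_uplift(self, X: np.ndarray) -> np.ndarray:
        """Plug-in CATE estimate u_hat(x) = y_hat_1(x) - y_hat_0(x), in (-1, 1)."""
        y1, y0, _ = self.forward_potential_outcomes(X)
        return y1 - y0

    # -------------------------------------------------------------- persistence

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()

    def save(self, path: str | Path) -> None:
        """Single-file parameter archive (.npz) plus a JSON config sidecar."""
        path = Path(path)
        np.savez(path, **self.params)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(self.config.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "UpliftNetwork":
        path = Path(path)
        if not path.suffix == ".npz":
            path = path.with_suffix(".npz")
        sidecar = path.with_suffix(path.suffix + ".json")
        config = NetworkConfig.from_dict(json.loads(sidecar.read_text()))
        net = cls(config)
        with np.load(path) as archive:
            net.set_params({k: archive[k] for k in archive.files})
        return net


def build_network(config: NetworkConfig) -> UpliftNetwork:
    """Deterministically initialize an UpliftNetwork from its config/seed."""
    return UpliftNetwork(config)


# ------------------------------------------------------------------- losses


def uplift_loss(
    y1: np.ndarray,
    y0: np.ndarray,
    t: np.ndarray,
    y: np.ndarray,
    return_grads: bool = False,
):
    """Factual binary cross-entropy on the exposed head.

    y_obs = t*y1 + (1-t)*y0; loss = mean BCE(y_obs, y).  The gradient flows
    only through the head matching each sample's observed arm.  Probabilities
    are clamped to [EPS, 1-EPS].
    """
    y1 = np.asarray(y1, dtype=float)
    y0 = np.asarray(y0, dtype=float)
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (y1.shape == y0.shape == t.shape == y.shape):
        raise ValueError("uplift_loss arguments must share one shape")
    n = y.size
    if n == 0:
        raise ValueError("uplift_loss needs at least one sample")
    p = np.clip(t * y1 + (1.0 - t) * y0, EPS, 1.0 - EPS)
    loss = float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    if not return_grads:
        return loss
    dp = (p - y) / (p * (1.0 - p)) / n
    return loss, t * dp, (1.0 - t) * dp


def fairness_penalty(
    u: np.ndarray,
    G: np.ndarray,
    E: np.ndarray,
    scope: str = "batch",
    return_grads: bool = False,
):
    """Squared group-mean uplift parity penalty over gender and education.

    (mean u | G=0  -  mean u | G=1)^2 + (mean u | E=0  -  mean u | E=1)^2,
    where a squared term contributes only when both cells of that attribute
    are non-empty within the evaluation scope (the vectors passed in); an
    attribute with an empty cell contributes 0.  ``scope`` is informational
    ("batch" or "epoch"): the caller decides which rows are in scope.
    """
    del scope
    u = np.asarray(u, dtype=float)
    penalty = 0.0
    du = np.zeros_like(u)
    for attr in (np.asarray(G), np.asarray(E)):
        m0 = attr == 0
        m1 = attr == 1
        n0, n1 = int(m0.sum()), int(m1.sum())
        if n0 == 0 or n1 == 0:
            continue
        diff = u[m0].mean() - u[m1].mean()
        penalty += diff**2
        if return_grads:
            du[m0] += 2.0 * diff / n0
            du[m1] -= 2.0 * diff / n1
    if not return_grads:
        return float(penalty)
    return float(penalty), du


def grl_forward(emb: np.ndarray) -> np.ndarray:
    """Gradient-reversal layer forward pass: the identity."""
    return emb


def grl_backward(d_emb: np.ndarray, lambda_d: float) -> np.ndarray:
    """Backward pass of the GRL: flip sign and scale by lambda_D."""
    if lambda_d < 0:
        raise ConfigError(f"lambda_d must be non-negative, got {lambda_d}")
    return -lambda_d * d_emb


def total_loss(
    l_uplift: float,
    l_domain: float,
    l_fair: float,
    lambda_d: float,
    lambda_f: float,
) -> LossBreakdown:
    """Weighted composite objective with its breakdown retained for logging."""
    if lambda_d < 0 or lambda_f < 0:
        raise ConfigError("loss weights must be non-negative")
    parts = (l_uplift, l_domain, l_fair)
    if not all(np.isfinite(parts)):
        raise FloatingPointError(f"non-finite loss component: {parts}")
    return LossBreakdown(
        l_uplift=float(l_uplift),
        l_domain=float(l_domain),
        l_fair=float(l_fair),
        lambda_d=float(lambda_d),
        lambda_f=float(lambda_f),
    )
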