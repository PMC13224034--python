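"""Training variants for the uplift backbone: NoDA, DANN, CDAN, CORAL, MMD.

All five methods share the same encoder/heads; they differ only in the
alignment term added to the factual cross-entropy:

* ``noda``  -- no alignment (two-head neural T-learner).
* ``dann``  -- adversarial K-way domain cross-entropy through the GRL.
* ``cdan``  -- conditional adversarial: the discriminator consumes
  [f(x), y0, y1], so the reversed gradient also reaches the heads.
* ``coral`` -- squared Frobenius mismatch of embedding covariances.
* ``mmd``   -- squared maximum mean discrepancy with a Gaussian kernel
  (median-heuristic bandwidth, biased V-statistic).

The adversarial weight lambda_D can follow a fixed value, a linear ramp, or
the classical sigmoid ramp in training progress p = epoch / epochs.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from .network import (
    EPS,
    ConfigError,
    LossBreakdown,
    NetworkConfig,
    UpliftNetwork,
    build_network,
    fairness_penalty,
    total_loss,
    uplift_loss,
)

__all__ = [
    "METHODS",
    "TrainConfig",
    "TrainedModel",
    "schedule_lambda",
    "domain_adversarial_penalty",
    "cdan_penalty",
    "coral_penalty",
    "mmd_penalty",
    "train",
]

METHODS = ("noda", "dann", "cdan", "coral", "mmd")

#: Final hyperparameter search ranges (lr log-uniform; others uniform).
SEARCH_RANGES = {
    "lr": (1e-4, 5e-4),
    "lambda_d": (0.1, 0.8),
    "lambda_f": (1.0, 15.0),
    "weight_decay": (1e-5, 1e-4),
}


@dataclass
class TrainConfig:
    """Resolved training configuration (one per run).

    Defaults use the midpoints of the documented search ranges where the
    protocol leaves a value open: lr 3e-4, weight_decay 5e-5, lambda_d 0.4.
    Batch size, epochs and patience are declared here, not inherited from any
    external protocol.
    """

    method: str = "noda"
    lambda_d: float = 0.4
    lambda_f: float = 0.0
    schedule: str = "fixed"
    schedule_gamma: float = 10.0
    lr: float = 3e-4
    weight_decay: float = 5e-5
    grad_clip: float = 1.0
    epochs: int = 40
    batch_size: int = 64
    patience: int = 10
    seed: int = 0
    val_fraction: float = 0.2
    fairness_scope: str = "epoch"
    hidden_widths: tuple[int, ...] = (128, 64)
    dropout: float = 0.30

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.lambda_d < 0 or self.lambda_f < 0:
            raise ConfigError("lambda_d and lambda_f must be non-negative")
        if self.schedule not in ("fixed", "linear", "sigmoid"):
            raise ConfigError(f"unknown schedule {self.schedule!r}")
        if self.fairness_scope not in ("batch", "epoch"):
            raise ConfigError(f"unknown fairness_scope {self.fairness_scope!r}")
        if not (0.0 < self.val_fraction < 1.0):
            raise ConfigError("val_fraction must be in (0, 1)")
        self.hidden_widths = tuple(int(w) for w in self.hidden_widths)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_widths"] = list(self.hidden_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


@dataclass
class TrainedModel:
    """A fitted run: final network (best validation-AUUC parameters restored),
    the resolved config, per-epoch history, and the index of the best epoch."""

    network: UpliftNetwork
    config: TrainConfig
    history: list[dict] = field(default_factory=list)
    best_epoch: int = 0

    def predict_uplift(self, X: np.ndarray) -> np.ndarray:
        return self.network.predict_uplift(X)

    def write_history_csv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(self.history[0]))
            writer.writeheader()
            writer.writerows(self.history)


# ----------------------------------------------------------------- schedules


def schedule_lambda(schedule: str, lambda_max: float, p: float, gamma: float = 10.0) -> float:
    """Adversarial-weight schedule at training progress p in [0, 1].

    fixed   -> lambda_max
    linear  -> lambda_max * p
    sigmoid -> lambda_max * (2 / (1 + exp(-gamma * p)) - 1)   (0 at p=0)
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"progress p must be in [0, 1], got {p}")
    if schedule == "fixed":
        return float(lambda_max)
    if schedule == "linear":
        return float(lambda_max * p)
    if schedule == "sigmoid":
        return float(lambda_max * (2.0 / (1.0 + np.exp(-gamma * p)) - 1.0))
    raise ConfigError(f"unknown schedule {schedule!r}")


# ----------------------------------------------------------------- penalties


def domain_adversarial_penalty(
    embedding: np.ndarray,
    domain_labels: np.ndarray,
    net: UpliftNetwork,
    return_grads: bool = False,
):
    """Mean K-way cross-entropy of the domain discriminator vs. true labels.

    With ``return_grads`` also returns (discriminator grads, d_embedding):
    the discriminator gradient is unreversed; the caller applies the GRL
    scaling -lambda_D to d_embedding before routing it into the encoder.
    """
    labels = np.asarray(domain_labels, dtype=int)
    K = net.config.num_domains
    if labels.size and (labels.min() < 0 or labels.max() >= K):
        raise ValueError(f"domain labels must lie in [0, {K}), got range "
                         f"[{labels.min()}, {labels.max()}]")
    probs, cache = net.discriminator_forward(embedding)
    n = labels.size
    p_true = np.clip(probs[np.arange(n), labels], EPS, 1.0)
    loss = float(-np.mean(np.log(p_true)))
    if not return_grads:
        return loss
    onehot = np.zeros_like(probs)
    onehot[np.arange(n), labels] = 1.0
    dlogits = (probs - onehot) / n
    disc_grads, dZ = net.discriminator_backward(cache, dlogits)
    return loss, disc_grads, dZ


def cdan_penalty(
    embedding: np.ndarray,
    y0: np.ndarray,
    y1: np.ndarray,
    domain_labels: np.ndarray,
    net: UpliftNetwork,
    return_grads: bool = False,
):
    """Conditional adversarial penalty on the concatenation [f(x), y0, y1].

    The grads variant returns (disc grads, d_embedding_direct, dy0, dy1); the
    reversed gradient reaches both the encoder (directly and through the
    heads) and the head parameters.
    """
    U = np.column_stack([embedding, np.asarray(y0, float), np.asarray(y1, float)])
    out = domain_adversarial_penalty(U, domain_labels, net, return_grads=return_grads)
    if not return_grads:
        return out
    loss, disc_grads, dU = out
    m = embedding.shape[1]
    return loss, disc_grads, dU[:, :m], dU[:, m], dU[:, m + 1]


def _covariance(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Zc = Z - Z.mean(axis=0, keepdims=True)
    return Zc.T @ Zc / (Z.shape[0] - 1), Zc


def coral_penalty(
    embedding_source: np.ndarray,
    embedding_target: np.ndarray,
    return_grads: bool = False,
):
    """Covariance alignment: ||C_s - C_t||_F^2 / (4 m^2) over sample covariances."""
    Zs = np.asarray(embedding_source, float)
    Zt = np.asarray(embedding_target, float)
    if Zs.shape[0] < 2 or Zt.shape[0] < 2:
        raise ValueError("coral_penalty needs at least 2 rows per side")
    m = Zs.shape[1]
    Cs, Zsc = _covariance(Zs)
    Ct, Ztc = _covariance(Zt)
    D = Cs - Ct
    value = float(np.sum(D * D) / (4.0 * m * m))
    if not return_grads:
        return value
    dZs = Zsc @ D / (m * m * (Zs.shape[0] - 1))
    dZt = -Ztc @ D / (m * m * (Zt.shape[0] - 1))
    return value, dZs, dZt


def _gauss_kernel(A: np.ndarray, B: np.ndarray, sigma2: float) -> np.ndarray:
    d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * sigma2))


def median_bandwidth(Z: np.ndarray) -> float:
    """Median pairwise Euclidean distance (off-diagonal) over the joint batch;
    falls back to 1.0 (with a warning) when every pairwise distance is zero."""
    n = Z.shape[0]
    if n < 2:
        return 1.0
    d2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2)
    off = d2[~np.eye(n, dtype=bool)]
    med = float(np.sqrt(np.median(off)))
    if med == 0.0:
        warnings.warn("all pairwise distances are zero; MMD bandwidth falls back to 1.0")
        return 1.0
    return med


def mmd_penalty(
    embedding_source: np.ndarray,
    embedding_target: np.ndarray,
    bandwidth: float | None = None,
    return_grads: bool = False,
):
    """Squared MMD (biased V-statistic) with a Gaussian kernel.

    The bandwidth defaults to the median pairwise distance over the joint
    batch and is treated as a constant in the gradient.
    """
    Zs = np.asarray(embedding_source, float)
    Zt = np.asarray(embedding_target, float)
    if Zs.shape[0] == 0 or Zt.shape[0] == 0:
        raise ValueError("mmd_penalty needs non-empty batches on both sides")
    if bandwidth is None:
        bandwidth = median_bandwidth(np.vstack([Zs, Zt]))
    s2 = bandwidth * bandwidth
    ns, nt = Zs.shape[0], Zt.shape[0]
    Kss = _gauss_kernel(Zs, Zs, s2)
    Ktt = _gauss_kernel(Zt, Zt, s2)
    Kst = _gauss_kernel(Zs, Zt, s2)
    value = float(Kss.mean() + Ktt.mean() - 2.0 * Kst.mean())
    if not return_grads:
        return value

    def _pair_grad(K: np.ndarray, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        # d/dA_i sum_j K_ij ||a_i - b_j||^2-style term: sum_j K_ij (a_i - b_j)
        return K.sum(axis=1)[:, None] * A - K @ B

    dZs = (-2.0 / (ns * ns * s2)) * _pair_grad(Kss, Zs, Zs) \
        + (2.0 / (ns * nt * s2)) * _pair_grad(Kst, Zs, Zt)
    dZt = (-2.0 / (nt * nt * s2)) * _pair_grad(Ktt, Zt, Zt) \
        + (2.0 / (ns * nt * s2)) * _pair_grad(Kst.T, Zt, Zs)
    return value, dZs, dZt


# ----------------------------------------------------------------- optimizer


class Adam:
    """Adam with L2 weight decay added to the gradient (torch-style)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 weight_decay: float = 0.0, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = {k: 0 for k in params}
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        for k, g in grads.items():
            p = self.params[k]
            if self.weight_decay:
                g = g + self.weight_decay * p
            self.t[k] += 1
            t = self.t[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**t)
            vhat = self.v[k] / (1 - self.b2**t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _accumulate(into: dict, grads: dict) -> None:
    for k, g in grads.items():
        if k in into:
            into[k] = into[k] + g
        else:
            into[k] = g


def _clip_group(grads: dict, keys: list[str], max_norm: float) -> None:
    """Scale the listed gradients so their joint L2 norm is at most max_norm.

    Clipping is applied per parameter group (uplift path vs. discriminator)
    so that a zero-weight adversarial branch cannot perturb the uplift-path
    update magnitudes."""
    if max_norm is None or max_norm <= 0:
        return
    present = [k for k in keys if k in grads]
    total = np.sqrt(sum(float(np.sum(grads[k] ** 2)) for k in present))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for k in present:
            grads[k] = grads[k] * scale


# -------------------------------------------------------------- training loop


def _epoch_rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(t) for t in tags)))


def train(
    data_sources,
    data_target: np.ndarray | None = None,
    config: TrainConfig | None = None,
    target_domain_id: int | None = None,
) -> TrainedModel:
    """Fit an uplift network on labeled source data, optionally aligning to an
    unlabeled target feature matrix.

    ``data_sources`` is a HarmonizedDataset (X, T, Y, D, G, E).  For the
    adversarial/alignment variants, ``data_target`` rows (features only) are
    interleaved with source batches; the target receives its own discriminator
    class.  Training is deterministic given (config.seed, data): batch order,
    dropout masks, and the validation split all derive from it.

    Early stopping monitors validation AUUC (20% of pooled source rows,
    stratified jointly on treatment and source domain) and restores the best
    parameters.  Gradients are clipped per parameter group at
    ``config.grad_clip``; lambda_D follows the configured schedule with
    progress p = epoch / epochs.
    """
    from .evaluate import uplift_curve  # local import to avoid a cycle

    if config is None:
        config = TrainConfig()
    method = config.method
    X = np.asarray(data_sources.X, float)
    T = np.asarray(data_sources.T, int)
    Y = np.asarray(data_sources.Y, int)
    D = np.asarray(data_sources.D, int)
    G = np.asarray(data_sources.G, int)
    E = np.asarray(data_sources.E, int)
    n, d = X.shape
    if len(np.unique(T)) < 2:
        raise ValueError("source data must contain both treatment values")

    # ---- validation split, stratified jointly on (T, domain)
    strata = T * 10 + D
    idx = np.arange(n)
    try:
        tr_idx, va_idx = train_test_split(
            idx, test_size=config.val_fraction, stratify=strata,
            random_state=config.seed % (2**32),
        )
    except ValueError as exc:
        raise ValueError(f"stratified validation split failed: {exc}") from exc
    for part, name in ((tr_idx, "training"), (va_idx, "validation")):
        if len(np.unique(T[part])) < 2:
            raise ValueError(f"{name} split lacks both treatment values")

    # ---- discriminator classes: source domains (sorted) + optional target class
    src_domains = np.unique(D)
    dom_remap = {int(dv): i for i, dv in enumerate(src_domains)}
    use_target = data_target is not None and method != "noda"
    K = len(src_domains) + (1 if use_target else 0)
    K = max(K, 2)
    target_class = len(src_domains)

    net = build_network(NetworkConfig(
        input_dim=d,
        hidden_widths=config.hidden_widths,
        dropout=config.dropout,
        num_domains=K,
        seed=config.seed,
        disc_extra_inputs=2 if method == "cdan" else 0,
    ))
    optim = Adam(net.params, lr=config.lr, weight_decay=config.weight_decay)
    uplift_keys = [k for k in net.params if k.startswith(("enc_", "h1_", "h0_"))]
    disc_keys = [k for k in net.params if k.startswith("disc_")]

    Xtr, Ttr, Ytr = X[tr_idx], T[tr_idx], Y[tr_idx]
    Gtr, Etr = G[tr_idx], E[tr_idx]
    Dtr = np.array([dom_remap[int(v)] for v in D[tr_idx]])
    Xva, Tva, Yva = X[va_idx], T[va_idx], Y[va_idx]
    Xtgt = None if data_target is None else np.asarray(data_target, float)

    adversarial = method in ("dann", "cdan")
    moment = method in ("coral", "mmd")

    history: list[dict] = []
    best_auuc = -np.inf
    best_epoch = -1
    best_params = net.copy_params()
    wait = 0

    for epoch in range(config.epochs):
        p = epoch / config.epochs
        lam_d = schedule_lambda(config.schedule, config.lambda_d, p, config.schedule_gamma)
        net.grl_weight = lam_d
        shuffle_rng = _epoch_rng(config.seed, 1, epoch)
        order = shuffle_rng.permutation(len(tr_idx))
        tgt_order = None
        if use_target and Xtgt is not None and len(Xtgt):
            tgt_order = _epoch_rng(config.seed, 4, epoch).permutation(len(Xtgt))
        sums = {"l_uplift": 0.0, "l_domain": 0.0, "l_fair": 0.0}
        n_batches = 0

        for step, start in enumerate(range(0, len(order), config.batch_size)):
            b = order[start:start + config.batch_size]
            Xb, Tb, Yb = Xtr[b], Ttr[b], Ytr[b]
            grads: dict[str, np.ndarray] = {}

            emb, cache = net.encoder_forward(
                Xb, train=True, dropout_rng=_epoch_rng(config.seed, 2, epoch, step))
            y1, y0 = net.heads_forward(emb)
            l_up, dy1, dy0 = uplift_loss(y1, y0, Tb, Yb, return_grads=True)
            l_fair_b = 0.0
            if config.lambda_f > 0 and config.fairness_scope == "batch":
                l_fair_b, du = fairness_penalty(
                    y1 - y0, Gtr[b], Etr[b], scope="batch", return_grads=True)
                dy1 = dy1 + config.lambda_f * du
                dy0 = dy0 - config.lambda_f * du
            head_grads, d_emb = net.heads_backward(emb, y1, y0, dy1, dy0)
            _accumulate(grads, head_grads)

            # ---- alignment term
            l_dom = 0.0
            if adversarial or moment:
                if use_target and tgt_order is not None and len(tgt_order):
                    # interleave: cycle target rows to match the source batch
                    pos = (step * config.batch_size) % len(tgt_order)
                    tb = np.concatenate([tgt_order[pos:pos + len(b)],
                                         tgt_order[:max(0, pos + len(b) - len(tgt_order))]])
                    Xtb = Xtgt[tb]
                    emb_t, cache_t = net.encoder_forward(
                        Xtb, train=True, dropout_rng=_epoch_rng(config.seed, 3, epoch, step))
                    src_emb, tgt_emb = emb, emb_t
                    dom_labels = np.concatenate([Dtr[b], np.full(len(tb), target_class)])
                else:
                    # no target supplied: align the first two source domains
                    present = np.unique(Dtr[b])
                    cache_t = None
                    msk0 = msk1 = None
                    if len(present) >= 2 and moment:
                        msk0 = Dtr[b] == present[0]
                        msk1 = Dtr[b] == present[1]
                        src_emb, tgt_emb = emb[msk0], emb[msk1]
                    else:
                        src_emb = tgt_emb = None
                    dom_labels = Dtr[b]

                if adversarial:
                    Zall = emb if cache_t is None else np.vstack([emb, emb_t])
                    if method == "dann":
                        l_dom, disc_grads, dZ = domain_adversarial_penalty(
                            Zall, dom_labels, net, return_grads=True)
                        d_emb_rev = -lam_d * dZ
                    else:  # cdan
                        if cache_t is None:
                            y1a, y0a = y1, y0
                        else:
                            y1t, y0t = net.heads_forward(emb_t)
                            y1a = np.concatenate([y1, y1t])
                            y0a = np.concatenate([y0, y0t])
                        l_dom, disc_grads, dZdir, dy0a, dy1a = cdan_penalty(
                            Zall, y0a, y1a, dom_labels, net, return_grads=True)
                        hg, d_emb_h = net.heads_backward(
                            Zall, y1a, y0a, -lam_d * dy1a, -lam_d * dy0a)
                        _accumulate(grads, hg)
                        d_emb_rev = -lam_d * dZdir + d_emb_h
                    _accumulate(grads, disc_grads)
                    ns = emb.shape[0]
                    d_emb = d_emb + d_emb_rev[:ns]
                    if cache_t is not None:
                        _accumulate(grads, net.encoder_backward(cache_t, d_emb_rev[ns:]))
                elif moment and src_emb is not None and (
                        method == "mmd" or (src_emb.shape[0] >= 2 and tgt_emb.shape[0] >= 2)):
                    pen = coral_penalty if method == "coral" else mmd_penalty
                    l_dom, dZs, dZt = pen(src_emb, tgt_emb, return_grads=True)
                    if cache_t is not None:
                        d_emb = d_emb + lam_d * dZs
                        _accumulate(grads, net.encoder_backward(cache_t, lam_d * dZt))
                    else:
                        dfull = np.zeros_like(emb)
                        dfull[msk0] = lam_d * dZs
                        dfull[msk1] = lam_d * dZt
                        d_emb = d_emb + dfull

            _accumulate(grads, net.encoder_backward(cache, d_emb))
            _clip_group(grads, uplift_keys, config.grad_clip)
            _clip_group(grads, disc_keys, config.grad_clip)
            optim.step(grads)

            breakdown = total_loss(l_up, l_dom, l_fair_b, lam_d, config.lambda_f)
            if not np.isfinite(breakdown.total):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}: {breakdown}")
            sums["l_uplift"] += l_up
            sums["l_domain"] += l_dom
            sums["l_fair"] += l_fair_b
            n_batches += 1

        # ---- epoch-scope fairness step (deterministic full pass, dropout off)
        if config.lambda_f > 0 and config.fairness_scope == "epoch":
            emb, cache = net.encoder_forward(Xtr, train=False)
            y1, y0 = net.heads_forward(emb)
            l_fair, du = fairness_penalty(y1 - y0, Gtr, Etr, scope="epoch", return_grads=True)
            head_grads, d_emb = net.heads_backward(
                emb, y1, y0, config.lambda_f * du, -config.lambda_f * du)
            grads = dict(head_grads)
            _accumulate(grads, net.encoder_backward(cache, d_emb))
            _clip_group(grads, uplift_keys, config.grad_clip)
            optim.step(grads)
            sums["l_fair"] = l_fair * n_batches  # report the epoch-level value

        mean_break = LossBreakdown(
            l_uplift=sums["l_uplift"] / max(n_batches, 1),
            l_domain=sums["l_domain"] / max(n_batches, 1),
            l_fair=sums["l_fair"] / max(n_batches, 1),
            lambda_d=lam_d,
            lambda_f=config.lambda_f,
        )
        val_auuc = uplift_curve(net.predict_uplift(Xva), Tva, Yva).auuc
        history.append({
            "epoch": epoch, "lambda_d": lam_d,
            "l_uplift": mean_break.l_uplift, "l_domain": mean_break.l_domain,
            "l_fair": mean_break.l_fair, "total": mean_break.total,
            "val_auuc": val_auuc,
        })
        if val_auuc > best_auuc:
            best_auuc = val_auuc
            best_epoch = epoch
            best_params = net.copy_params()
            wait = 0
        else:
            wait += 1
            if wait >= config.patience:
                break

    net.set_params(best_params)
    return TrainedModel(network=net, config=config, history=history, best_epoch=best_epoch)
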