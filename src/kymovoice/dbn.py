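"""Gaussian–Bernoulli RBMs, contrastive divergence, and deep belief networks.

The bottom restricted Boltzmann machine has real-valued (Gaussian) visible
units with per-unit noise SD ``sigma`` and binary hidden units; its energy is

    E(v, h) = sum_j (v_j - C_j)^2 / (2 sigma_j^2)
              - sum_i c_i h_i
              - sum_{j,i} (v_j / sigma_j) h_i W_ji

which gives the conditionals ``p(h_i = 1 | v) = logistic(c_i + sum_j (v_j /
sigma_j) W_ji)`` and ``v_j | h ~ Normal(C_j + sigma_j sum_i W_ji h_i,
sigma_j)``.  Upper layers are Bernoulli–Bernoulli RBMs trained on the hidden
activation probabilities of the layer below.  Training is contrastive
divergence (CD-k): the weight increment is the learning rate times the
difference between the data-side and reconstruction-side correlations
``<(v_j / sigma_j) h_i>``, with momentum on all increments.

A deep belief network is a greedily pretrained stack of such RBMs plus a
softmax class-probability head; supervised fine-tuning backpropagates the
mean cross-entropy through the deterministic sigmoid activations of every
layer.  ``sigma`` is fixed at 1: inputs are expected min–max scaled to
[0, 1] (done by the pipeline), under which unit noise SD is a standard and
stable choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RBMParams",
    "TrainConfig",
    "DBNModel",
    "energy",
    "hidden_given_visible",
    "visible_given_hidden",
    "cd_gradient",
    "cd_update",
    "pretrain_stack",
    "fine_tune",
    "predict",
]

_SCHEMA_VERSION = 1


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class RBMParams:
    """Parameters of one RBM layer.

    ``W`` has shape (n_visible, n_hidden); ``b_vis`` are the visible offsets
    ``C_j`` (intensity units for the Gaussian layer), ``b_hid`` the hidden
    biases ``c_i``.  ``visible_type`` selects Gaussian or Bernoulli visible
    units; ``sigma`` is the per-visible-unit Gaussian noise SD (all ones for
    Bernoulli layers, where it is inert).
    """

    W: np.ndarray
    b_vis: np.ndarray
    b_hid: np.ndarray
    sigma: np.ndarray
    visible_type: str = "gaussian"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        self.b_vis = np.asarray(self.b_vis, dtype=np.float64)
        self.b_hid = np.asarray(self.b_hid, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        nv, nh = self.W.shape
        if self.b_vis.shape != (nv,) or self.b_hid.shape != (nh,):
            raise ValueError("bias shapes inconsistent with W")
        if self.sigma.shape != (nv,):
            raise ValueError("sigma must have one entry per visible unit")
        if (self.sigma <= 0).any():
            raise ValueError("sigma must be positive elementwise")
        if self.visible_type not in ("gaussian", "bernoulli"):
            raise ValueError("visible_type must be 'gaussian' or 'bernoulli'")

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "RBMParams":
        return RBMParams(
            self.W.copy(), self.b_vis.copy(), self.b_hid.copy(),
            self.sigma.copy(), self.visible_type,
        )


def init_rbm(
    n_visible: int,
    n_hidden: int,
    rng: np.random.Generator,
    visible_type: str = "gaussian",
    weight_sd: float = 0.01,
) -> RBMParams:
    """Small-Gaussian weight initialization, zero biases, unit sigma."""
    return RBMParams(
        W=rng.normal(0.0, weight_sd, size=(n_visible, n_hidden)),
        b_vis=np.zeros(n_visible),
        b_hid=np.zeros(n_hidden),
        sigma=np.ones(n_visible),
        visible_type=visible_type,
    )


@dataclass(frozen=True)
class TrainConfig:
    """Contrastive-divergence / fine-tuning settings.

    ``learning_rate`` is the step size applied to the correlation difference;
    ``cd_steps`` the number of alternating Gibbs passes (CD-k, default k=1);
    momentum smooths all parameter increments.
    """

    learning_rate: float = 0.05
    momentum: float = 0.5
    cd_steps: int = 1
    batch_size: int = 32
    epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.cd_steps < 1:
            raise ValueError("cd_steps must be >= 1")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size >= 1 and epochs >= 0 required")


# ---------------------------------------------------------------------------
# Energy and conditionals


def _check_vh(v: np.ndarray, h: np.ndarray, params: RBMParams) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(v, dtype=np.float64)
    h = np.asarray(h, dtype=np.float64)
    if v.shape[-1] != params.n_visible or h.shape[-1] != params.n_hidden:
        raise ValueError(
            f"shape mismatch: v{v.shape}, h{h.shape} vs "
            f"({params.n_visible} visible, {params.n_hidden} hidden)"
        )
    return v, h


def energy(v: np.ndarray, h: np.ndarray, params: RBMParams) -> float | np.ndarray:
    """Joint energy E(v, h) of one (or a batch of) visible/hidden states."""
    v, h = _check_vh(v, h, params)
    if params.visible_type == "gaussian":
        quad = (((v - params.b_vis) ** 2) / (2.0 * params.sigma**2)).sum(axis=-1)
        inter = np.einsum("...j,...i,ji->...", v / params.sigma, h, params.W)
    else:
        quad = -(v * params.b_vis).sum(axis=-1)
        inter = np.einsum("...j,...i,ji->...", v, h, params.W)
    e = quad - (h * params.b_hid).sum(axis=-1) - inter
    return float(e) if e.ndim == 0 else e


def hidden_given_visible(v: np.ndarray, params: RBMParams) -> np.ndarray:
    """Activation probabilities p(h_i = 1 | v); v may be a batch."""
    v = np.asarray(v, dtype=np.float64)
    if v.shape[-1] != params.n_visible:
        raise ValueError(f"v has {v.shape[-1]} features, expected {params.n_visible}")
    return _sigmoid(params.b_hid + (v / params.sigma) @ params.W)


def visible_given_hidden(h: np.ndarray, params: RBMParams) -> np.ndarray:
    """Gaussian means (or Bernoulli probabilities) of p(v | h); h may be a batch."""
    h = np.asarray(h, dtype=np.float64)
    if h.shape[-1] != params.n_hidden:
        raise ValueError(f"h has {h.shape[-1]} units, expected {params.n_hidden}")
    pre = params.b_vis + params.sigma * (h @ params.W.T)
    if params.visible_type == "gaussian":
        return pre
    return _sigmoid(pre)  # logistic(C + W h); sigma is all ones here


# ---------------------------------------------------------------------------
# Contrastive divergence


def cd_gradient(
    batch: np.ndarray,
    params: RBMParams,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """CD-k estimate of the log-likelihood gradient on one batch.

    Returns ``(dW, db_vis, db_hid, reconstruction_error)`` where ``dW`` is
    the data-side minus reconstruction-side correlation ``<(v/sigma) h>``
    (ascent direction, before the learning rate).  The data-side hidden term
    uses the exact activation probabilities p(h | v); the reconstruction
    comes from ``cd_steps`` alternating Gibbs passes with binary hidden
    samples and, for Gaussian layers, mean-field visible reconstructions.
    """
    v0 = np.asarray(batch, dtype=np.float64)
    if v0.ndim != 2 or v0.shape[0] == 0:
        raise ValueError("batch must be a nonempty 2-D array")
    if np.isnan(v0).any():
        raise ValueError("batch contains NaN")
    b = v0.shape[0]
    ph0 = hidden_given_visible(v0, params)
    h = (rng.random(ph0.shape) < ph0).astype(np.float64)
    for _ in range(cfg.cd_steps):
        vis = visible_given_hidden(h, params)
        if params.visible_type == "bernoulli":
            vk = (rng.random(vis.shape) < vis).astype(np.float64)
        else:
            vk = vis  # mean-field reconstruction for Gaussian visibles
        phk = hidden_given_visible(vk, params)
        h = (rng.random(phk.shape) < phk).astype(np.float64)
    dW = ((v0 / params.sigma).T @ ph0 - (vk / params.sigma).T @ phk) / b
    db_vis = ((v0 - vk) / params.sigma**2).mean(axis=0)
    db_hid = (ph0 - phk).mean(axis=0)
    # reconstruction quality is logged against the mean-field reconstruction
    # (for Bernoulli layers the sampled one has an irreducible p(1-p) floor)
    recon_err = float(np.mean((v0 - vis) ** 2))
    return dW, db_vis, db_hid, recon_err


def cd_update(
    batch: np.ndarray,
    params: RBMParams,
    cfg: TrainConfig,
    rng: np.random.Generator,
    velocity: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> tuple[RBMParams, tuple[np.ndarray, np.ndarray, np.ndarray], float]:
    """One momentum-smoothed CD step; returns (new params, velocity, recon error)."""
    dW, dbv, dbh, err = cd_gradient(batch, params, cfg, rng)
    if velocity is None:
        vW = np.zeros_like(params.W)
        vbv = np.zeros_like(params.b_vis)
        vbh = np.zeros_like(params.b_hid)
    else:
        vW, vbv, vbh = velocity
    vW = cfg.momentum * vW + cfg.learning_rate * dW
    vbv = cfg.momentum * vbv + cfg.learning_rate * dbv
    vbh = cfg.momentum * vbh + cfg.learning_rate * dbh
    new = params.copy()
    new.W += vW
    new.b_vis += vbv
    new.b_hid += vbh
    return new, (vW, vbv, vbh), err


# ---------------------------------------------------------------------------
# DBN


@dataclass
class DBNModel:
    """A stack of RBM layers plus an optional softmax classification head."""

    layers: list[RBMParams]
    head_W: np.ndarray | None = None
    head_b: np.ndarray | None = None
    classes: np.ndarray | None = None
    recon_errors: list[list[float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("a DBN needs at least one RBM layer")
        for lower, upper in zip(self.layers, self.layers[1:]):
            if lower.n_hidden != upper.n_visible:
                raise ValueError("adjacent layer dimensions do not match")
        if self.head_W is not None and self.head_W.shape[0] != self.layers[-1].n_hidden:
            raise ValueError("head input size must equal top hidden size")

    @property
    def n_features(self) -> int:
        return self.layers[0].n_visible

    def forward_hidden(self, X: np.ndarray) -> np.ndarray:
        """Deterministic forward pass: sigmoid activation probabilities per layer."""
        a = np.asarray(X, dtype=np.float64)
        for layer in self.layers:
            a = hidden_given_visible(a, layer)
        return a

    def save(self, path: str | Path) -> None:
        blob = {
            "schema_version": _SCHEMA_VERSION,
            "layers": [
                {
                    "W": lay.W.tolist(),
                    "b_vis": lay.b_vis.tolist(),
                    "b_hid": lay.b_hid.tolist(),
                    "sigma": lay.sigma.tolist(),
                    "visible_type": lay.visible_type,
                }
                for lay in self.layers
            ],
            "head_W": None if self.head_W is None else self.head_W.tolist(),
            "head_b": None if self.head_b is None else self.head_b.tolist(),
            "classes": None if self.classes is None else np.asarray(self.classes).tolist(),
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path: str | Path) -> "DBNModel":
        blob = json.loads(Path(path).read_text())
        if blob.get("schema_version") != _SCHEMA_VERSION:
            raise ValueError("unsupported model schema version")
        layers = [
            RBMParams(
                np.array(d["W"]), np.array(d["b_vis"]), np.array(d["b_hid"]),
                np.array(d["sigma"]), d["visible_type"],
            )
            for d in blob["layers"]
        ]
        return cls(
            layers=layers,
            head_W=None if blob["head_W"] is None else np.array(blob["head_W"]),
            head_b=None if blob["head_b"] is None else np.array(blob["head_b"]),
            classes=None if blob["classes"] is None else np.array(blob["classes"]),
        )


def pretrain_stack(
    data: np.ndarray,
    layer_sizes: list[int],
    cfg: TrainConfig,
    visible_sigma: np.ndarray | None = None,
) -> DBNModel:
    """Greedy layer-wise unsupervised pretraining of an RBM stack.

    The first layer has Gaussian visible units and is trained on ``data``
    directly; each subsequent Bernoulli–Bernoulli layer is trained on the
    hidden activation probabilities of the layer below.  Mean reconstruction
    error per epoch is logged per layer.

    ``visible_sigma`` fixes the per-unit noise SD of the Gaussian layer
    (default all ones).  Matching it to the per-feature SD of the scaled
    training data is strongly recommended: a sigma far above the data scale
    drowns the signal in model noise and stalls both contrastive-divergence
    learning and later fine-tuning.
    """
    X = np.asarray(data, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("data must be a nonempty 2-D array")
    if not layer_sizes or any(s <= 0 for s in layer_sizes):
        raise ValueError("layer sizes must be positive")
    rng = np.random.default_rng(cfg.seed)
    layers: list[RBMParams] = []
    histories: list[list[float]] = []
    inp = X
    for li, size in enumerate(layer_sizes):
        vtype = "gaussian" if li == 0 else "bernoulli"
        params = init_rbm(inp.shape[1], size, rng, visible_type=vtype)
        if li == 0 and visible_sigma is not None:
            params.sigma = np.broadcast_to(
                np.asarray(visible_sigma, dtype=np.float64), (inp.shape[1],)
            ).copy()
            if (params.sigma <= 0).any():
                raise ValueError("visible_sigma must be positive")
        velocity = None
        history = []
        n = inp.shape[0]
        for _epoch in range(cfg.epochs):
            order = rng.permutation(n)
            errs = []
            for start in range(0, n, cfg.batch_size):
                batch = inp[order[start : start + cfg.batch_size]]
                params, velocity, err = cd_update(batch, params, cfg, rng, velocity)
                errs.append(err)
            history.append(float(np.mean(errs)))
        layers.append(params)
        histories.append(history)
        inp = hidden_given_visible(inp, params)
    return DBNModel(layers=layers, recon_errors=histories)


# ---------------------------------------------------------------------------
# Supervised fine-tuning


def _forward(model: DBNModel, X: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
    activations = [np.asarray(X, dtype=np.float64)]
    for layer in model.layers:
        activations.append(hidden_given_visible(activations[-1], layer))
    logits = activations[-1] @ model.head_W + model.head_b
    logits = logits - logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    proba = expl / expl.sum(axis=1, keepdims=True)
    return activations, proba


def _loss_and_grads(
    model: DBNModel, X: np.ndarray, onehot: np.ndarray
) -> tuple[float, dict]:
    """Mean cross-entropy and its analytic gradients for head and all layers."""
    acts, proba = _forward(model, X)
    n = X.shape[0]
    loss = float(-np.mean(np.sum(onehot * np.log(proba + 1e-12), axis=1)))
    delta = (proba - onehot) / n  # d loss / d logits
    grads: dict = {
        "head_W": acts[-1].T @ delta,
        "head_b": delta.sum(axis=0),
        "layers": [],
    }
    da = delta @ model.head_W.T
    for li in range(len(model.layers) - 1, -1, -1):
        layer = model.layers[li]
        a_out = acts[li + 1]
        dz = da * a_out * (1.0 - a_out)
        gW = (acts[li] / layer.sigma).T @ dz
        gb = dz.sum(axis=0)
        grads["layers"].insert(0, {"W": gW, "b_hid": gb})
        if li > 0:
            da = (dz @ layer.W.T) / layer.sigma
    return loss, grads


def fine_tune(
    model: DBNModel,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
) -> DBNModel:
    """Supervised fine-tuning: attach a softmax head and run backpropagation.

    All RBM layers and the head are updated by momentum SGD on the mean
    cross-entropy of the predicted class distribution.  The full-training
    loss is monitored every epoch and the learning rate is halved when an
    epoch *diverges* (loss grows by more than 25% relative); transient
    small increases are deliberately tolerated — momentum must be able to
    carry the parameters through the flat symmetric saddle at which a
    small-weight network starts, and enforcing a strictly non-increasing
    loss trajectory empirically pins training to that saddle.
    ``epochs == 0`` attaches an initialized head without changing any
    layer.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("fine-tuning needs at least 2 classes")
    rng = np.random.default_rng(cfg.seed + 1)
    model = DBNModel(
        layers=[lay.copy() for lay in model.layers],
        head_W=rng.normal(0.0, 0.01, size=(model.layers[-1].n_hidden, len(classes))),
        head_b=np.zeros(len(classes)),
        classes=classes,
        recon_errors=[list(h) for h in model.recon_errors],
    )
    onehot = (y[:, None] == classes[None, :]).astype(np.float64)
    n = X.shape[0]
    lr = cfg.learning_rate
    prev_loss, _ = _loss_and_grads(model, X, onehot)
    vel: dict | None = None
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            _, grads = _loss_and_grads(model, X[sel], onehot[sel])
            if vel is None:
                vel = {
                    "head_W": np.zeros_like(model.head_W),
                    "head_b": np.zeros_like(model.head_b),
                    "layers": [
                        {"W": np.zeros_like(l.W), "b_hid": np.zeros_like(l.b_hid)}
                        for l in model.layers
                    ],
                }
            vel["head_W"] = cfg.momentum * vel["head_W"] - lr * grads["head_W"]
            vel["head_b"] = cfg.momentum * vel["head_b"] - lr * grads["head_b"]
            model.head_W += vel["head_W"]
            model.head_b += vel["head_b"]
            for l, g, v in zip(model.layers, grads["layers"], vel["layers"]):
                v["W"] = cfg.momentum * v["W"] - lr * g["W"]
                v["b_hid"] = cfg.momentum * v["b_hid"] - lr * g["b_hid"]
                l.W += v["W"]
                l.b_hid += v["b_hid"]
        loss, _ = _loss_and_grads(model, X, onehot)
        if loss > 1.25 * prev_loss + 1e-6:  # divergence safeguard only
            vel = None
            lr *= 0.5
        prev_loss = loss
    return model


def predict(
    model: DBNModel,
    samples: np.ndarray,
    hamming_tiebreak: bool = False,
    class_codes: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels for a batch of samples.

    With ``hamming_tiebreak=True`` and per-class binary prototype codes of
    the top hidden layer, near-ties between the top two class probabilities
    (gap below 1e-9) are resolved by the Hamming distance between the
    sample's binarized top activation and the class codes; this is off by
    default.
    """
    if model.head_W is None or model.classes is None:
        raise ValueError("model has no classification head; run fine_tune first")
    X = np.asarray(samples, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model ({model.n_features})"
        )
    acts, proba = _forward(model, X)
    winners = np.argmax(proba, axis=1)
    if hamming_tiebreak and class_codes is not None:
        top_sorted = np.sort(proba, axis=1)
        tied = (top_sorted[:, -1] - top_sorted[:, -2]) < 1e-9
        if tied.any():
            codes = (acts[-1][tied] >= 0.5).astype(int)
            dists = (codes[:, None, :] != class_codes[None, :, :]).sum(axis=2)
            winners[tied] = np.argmin(dists, axis=1)
    return proba, model.classes[winners]
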