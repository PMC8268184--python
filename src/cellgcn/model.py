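"""The sigGCN-style multimodal classifier.

Two parallel branches read the same normalized expression vector x in R^N:

* a spectral GCN encoder — F Chebyshev-polynomial filters of order K over the
  rescaled gene-graph Laplacian (conv_f = sum_k beta_{f,k} T_k(L~) x), ReLU,
  1-D max-pooling over contiguous blocks of p genes, flatten, dense -> 32
  (theta1) — regularized by a linear decoder that reconstructs x from theta1;
* a shallow NN — dense N -> 256 -> 32 with ReLU (theta2).

theta3 = [theta1, theta2] feeds a softmax output layer over the n cell types.
The training loss is lambda1 * NLL + lambda2 * per-cell sum-of-squares
reconstruction error + lambda3 * sum of squared parameters, minimized by
mini-batch SGD with momentum.  All forward and backward passes are explicit
numpy; gradients are validated against finite differences in the test suite.

A cell may be rejected as "unassigned" when its top softmax probability falls
below a threshold (0.65 by convention); the argmax label is retained next to
the flag so metrics can be computed both including and excluding rejections.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .graph import ScaledLaplacian, chebyshev_basis

PROB_FLOOR = 1e-12  # clip before log so an exactly-zero probability is finite


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    ``gcn_enabled=False`` drops the GCN branch and decoder entirely (the
    classifier then sees only theta2); this is the NN-only ablation.
    """

    n_genes: int = 1000
    cheb_order: int = 5          # K: receptive field of the spectral filter
    n_filters: int = 5           # F
    pool_size: int = 8           # p: genes merged per max-pool block
    gcn_embed_dim: int = 32
    nn_hidden_dims: tuple[int, int] = (256, 32)
    n_classes: int = 2
    lambda_cla: float = 1.0
    lambda_rec: float = 1.0
    lambda_reg: float = 1e-4
    batch_size: int = 64
    epochs: int = 50
    learning_rate: float = 0.01
    momentum: float = 0.9
    seed: int = 0
    reject_threshold: float | None = None
    conv_bias: bool = True
    gcn_enabled: bool = True

    def __post_init__(self) -> None:
        for name in ("n_genes", "cheb_order", "n_filters", "pool_size",
                     "gcn_embed_dim", "n_classes", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        self.nn_hidden_dims = tuple(self.nn_hidden_dims)
        if any(h < 1 for h in self.nn_hidden_dims) or len(self.nn_hidden_dims) != 2:
            raise ValueError("nn_hidden_dims must be two positive sizes")
        for name in ("lambda_cla", "lambda_rec", "lambda_reg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.reject_threshold is not None and not (0.0 <= self.reject_threshold <= 1.0):
            raise ValueError("reject_threshold must be in [0, 1]")

    @property
    def pooled_nodes(self) -> int:
        return -(-self.n_genes // self.pool_size)  # ceil(N / p)

    @property
    def concat_dim(self) -> int:
        d = self.nn_hidden_dims[1]
        if self.gcn_enabled:
            d += self.gcn_embed_dim
        return d

    def parameter_count(self) -> int:
        """Closed-form trainable-parameter count for this architecture."""
        n, f, k = self.n_genes, self.n_filters, self.cheb_order
        h1, h2 = self.nn_hidden_dims
        total = n * h1 + h1 + h1 * h2 + h2                      # NN branch
        total += self.concat_dim * self.n_classes + self.n_classes  # output layer
        if self.gcn_enabled:
            total += f * k                                      # Chebyshev coefficients
            if self.conv_bias:
                total += f
            total += self.pooled_nodes * f * self.gcn_embed_dim + self.gcn_embed_dim
            total += self.gcn_embed_dim * n + n                 # decoder
        return total


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


@dataclass
class PredictionResult:
    """Per-cell class probabilities, argmax labels, and the rejection mask."""

    probabilities: np.ndarray          # M x n, rows on the simplex
    predicted_labels: np.ndarray       # argmax class names (kept even when rejected)
    unassigned_mask: np.ndarray        # True where max prob < reject_threshold
    classes: list[str]
    cell_ids: list[str] | None = None

    @property
    def max_probability(self) -> np.ndarray:
        return self.probabilities.max(axis=1)


class SigGCNModel:
    """Trainable parameters plus the forward/backward machinery.

    Parameters live in ``self.params`` (name -> ndarray); gradients of the
    total loss are produced by :meth:`loss_and_grads` for the SGD loop and
    the finite-difference checks.
    """

    def __init__(self, config: ModelConfig, classes: Sequence[str],
                 gene_ids: Sequence[str] | None = None):
        if len(classes) != config.n_classes:
            raise ValueError("classes length must equal config.n_classes")
        self.config = config
        self.classes = list(classes)
        self.gene_ids = None if gene_ids is None else list(gene_ids)
        self.params: dict[str, np.ndarray] = {}
        self._init_params()

    # -- initialization -----------------------------------------------------

    def _init_params(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        n, f, k = cfg.n_genes, cfg.n_filters, cfg.cheb_order
        h1, h2 = cfg.nn_hidden_dims
        p = self.params
        if cfg.gcn_enabled:
            flat = cfg.pooled_nodes * f
            p["beta"] = _glorot(rng, k, 1, (f, k))
            if cfg.conv_bias:
                p["conv_bias"] = np.zeros(f)
            p["W_gcn"] = _glorot(rng, flat, cfg.gcn_embed_dim, (flat, cfg.gcn_embed_dim))
            p["b_gcn"] = np.zeros(cfg.gcn_embed_dim)
            p["W_dec"] = _glorot(rng, cfg.gcn_embed_dim, n, (cfg.gcn_embed_dim, n))
            p["b_dec"] = np.zeros(n)
        p["W_nn1"] = _glorot(rng, n, h1, (n, h1))
        p["b_nn1"] = np.zeros(h1)
        p["W_nn2"] = _glorot(rng, h1, h2, (h1, h2))
        p["b_nn2"] = np.zeros(h2)
        p["W_out"] = _glorot(rng, cfg.concat_dim, cfg.n_classes,
                             (cfg.concat_dim, cfg.n_classes))
        p["b_out"] = np.zeros(cfg.n_classes)

    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    # -- flat-vector access (finite-difference checks, checkpoints) ---------

    def get_flat(self) -> np.ndarray:
        return np.concatenate([self.params[k].ravel() for k in sorted(self.params)])

    def set_flat(self, vec: np.ndarray) -> None:
        i = 0
        for k in sorted(self.params):
            p = self.params[k]
            p[...] = vec[i:i + p.size].reshape(p.shape)
            i += p.size

    # -- forward pieces ------------------------------------------------------

    def gcn_forward(self, lap: ScaledLaplacian, x_batch: np.ndarray,
                    return_cache: bool = False):
        """GCN branch: Chebyshev conv -> ReLU -> max-pool -> dense -> ReLU.

        Returns (theta1 [B x embed], feature_map [B x N x F]); with
        ``return_cache`` also the intermediates needed for backprop.
        """
        cfg = self.config
        x_batch = np.atleast_2d(np.asarray(x_batch, dtype=float))
        b, n = x_batch.shape
        if n != cfg.n_genes or lap.n_nodes != n:
            raise ValueError(f"input has {n} genes, model/graph expect "
                             f"{cfg.n_genes}/{lap.n_nodes}")
        # T: K x B x N stack of Chebyshev-filtered signals (input is a leaf,
        # so no gradient flows through the Laplacian application).
        t = chebyshev_basis(lap, x_batch.T, cfg.cheb_order).transpose(0, 2, 1)
        pre = np.einsum("fk,kbn->bnf", self.params["beta"], t)
        if cfg.conv_bias:
            pre = pre + self.params["conv_bias"]
        fmap = np.maximum(pre, 0.0)
        # contiguous max-pool over the node axis, zero-padded tail
        pn, p = cfg.pooled_nodes, cfg.pool_size
        pad = pn * p - n
        padded = np.pad(fmap, ((0, 0), (0, pad), (0, 0))) if pad else fmap
        blocks = padded.reshape(b, pn, p, cfg.n_filters)
        pool_arg = blocks.argmax(axis=2)
        pooled = blocks.max(axis=2)
        flat = pooled.reshape(b, pn * cfg.n_filters)
        z1 = flat @ self.params["W_gcn"] + self.params["b_gcn"]
        theta1 = np.maximum(z1, 0.0)
        if not return_cache:
            return theta1, fmap
        cache = {"t": t, "pre": pre, "pool_arg": pool_arg, "flat": flat,
                 "z1": z1, "pad": pad, "shape": (b, n)}
        return theta1, fmap, cache

    def decode(self, theta1: np.ndarray) -> np.ndarray:
        """Linear decoder: reconstruct the N-gene expression row from theta1."""
        return np.atleast_2d(theta1) @ self.params["W_dec"] + self.params["b_dec"]

    def nn_forward(self, x_batch: np.ndarray, return_cache: bool = False):
        """NN branch: dense N -> 256 -> 32, ReLU after each layer."""
        x_batch = np.atleast_2d(np.asarray(x_batch, dtype=float))
        z1 = x_batch @ self.params["W_nn1"] + self.params["b_nn1"]
        h1 = np.maximum(z1, 0.0)
        z2 = h1 @ self.params["W_nn2"] + self.params["b_nn2"]
        theta2 = np.maximum(z2, 0.0)
        if not return_cache:
            return theta2
        return theta2, {"h1": h1, "z1": z1, "z2": z2}

    def classify(self, theta1: np.ndarray | None, theta2: np.ndarray) -> np.ndarray:
        """Concatenate branch features (GCN first) and softmax over classes."""
        theta2 = np.atleast_2d(theta2)
        if self.config.gcn_enabled:
            theta3 = np.concatenate([np.atleast_2d(theta1), theta2], axis=1)
        else:
            theta3 = theta2
        logits = theta3 @ self.params["W_out"] + self.params["b_out"]
        return _softmax(logits)

    def forward(self, lap: ScaledLaplacian | None, x_batch: np.ndarray) -> np.ndarray:
        """Full forward pass to class probabilities."""
        theta2 = self.nn_forward(x_batch)
        theta1 = None
        if self.config.gcn_enabled:
            theta1, _ = self.gcn_forward(lap, x_batch)
        return self.classify(theta1, theta2)

    # -- losses --------------------------------------------------------------

    def regularization_loss(self) -> float:
        """Sum of squares over every trainable parameter."""
        return float(sum(np.sum(v * v) for v in self.params.values()))

    def loss_and_grads(self, lap: ScaledLaplacian | None, x_batch: np.ndarray,
                       y_batch: np.ndarray):
        """Total loss, its components, and analytic gradients for one batch.

        Returns (losses dict, grads dict keyed like ``self.params``).
        """
        cfg = self.config
        x_batch = np.atleast_2d(np.asarray(x_batch, dtype=float))
        b = x_batch.shape[0]
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        theta2, nn_cache = self.nn_forward(x_batch, return_cache=True)
        if cfg.gcn_enabled:
            theta1, fmap, g_cache = self.gcn_forward(lap, x_batch, return_cache=True)
            theta3 = np.concatenate([theta1, theta2], axis=1)
            x_hat = theta1 @ p["W_dec"] + p["b_dec"]
        else:
            theta1, x_hat = None, None
            theta3 = theta2

        logits = theta3 @ p["W_out"] + p["b_out"]
        probs = _softmax(logits)
        l_cla = classification_loss(probs, y_batch)
        l_rec = reconstruction_loss(x_batch, x_hat) if cfg.gcn_enabled else 0.0
        l_reg = self.regularization_loss()
        total = total_loss(l_cla, l_rec, l_reg,
                           cfg.lambda_cla, cfg.lambda_rec, cfg.lambda_reg)

        # ---- backward ----
        one_hot = np.zeros_like(probs)
        one_hot[np.arange(b), y_batch] = 1.0
        d_logits = cfg.lambda_cla * (probs - one_hot) / b
        grads["W_out"] += theta3.T @ d_logits
        grads["b_out"] += d_logits.sum(axis=0)
        d_theta3 = d_logits @ p["W_out"].T

        if cfg.gcn_enabled:
            e = cfg.gcn_embed_dim
            d_theta1 = d_theta3[:, :e].copy()
            d_theta2 = d_theta3[:, e:].copy()
            # decoder / reconstruction
            d_xhat = cfg.lambda_rec * 2.0 * (x_hat - x_batch) / b
            grads["W_dec"] += theta1.T @ d_xhat
            grads["b_dec"] += d_xhat.sum(axis=0)
            d_theta1 += d_xhat @ p["W_dec"].T
            # dense GCN head
            d_z1 = d_theta1 * (g_cache["z1"] > 0)
            grads["W_gcn"] += g_cache["flat"].T @ d_z1
            grads["b_gcn"] += d_z1.sum(axis=0)
            d_flat = d_z1 @ p["W_gcn"].T
            # un-pool: route gradient to the argmax slot of each block
            pn, ps, f = cfg.pooled_nodes, cfg.pool_size, cfg.n_filters
            n = cfg.n_genes
            d_pool = d_flat.reshape(b, pn, f)
            d_blocks = np.zeros((b, pn, ps, f))
            bi, ni, fi = np.ogrid[:b, :pn, :f]
            d_blocks[bi, ni, g_cache["pool_arg"], fi] = d_pool
            d_fmap = d_blocks.reshape(b, pn * ps, f)[:, :n, :]
            d_pre = d_fmap * (g_cache["pre"] > 0)
            grads["beta"] += np.einsum("bnf,kbn->fk", d_pre, g_cache["t"])
            if cfg.conv_bias:
                grads["conv_bias"] += d_pre.sum(axis=(0, 1))
        else:
            d_theta2 = d_theta3

        d_z2 = d_theta2 * (nn_cache["z2"] > 0)
        grads["W_nn2"] += nn_cache["h1"].T @ d_z2
        grads["b_nn2"] += d_z2.sum(axis=0)
        d_h1 = (d_z2 @ p["W_nn2"].T) * (nn_cache["z1"] > 0)
        grads["W_nn1"] += x_batch.T @ d_h1
        grads["b_nn1"] += d_h1.sum(axis=0)

        for k in grads:
            grads[k] += 2.0 * cfg.lambda_reg * p[k]

        losses = {"total": total, "cla": l_cla, "rec": l_rec, "reg": l_reg}
        return losses, grads

    # -- checkpointing -------------------------------------------------------

    def save(self, path) -> None:
        """Single-file archive: parameters + config + gene order + classes."""
        meta = {"config": asdict(self.config), "classes": self.classes,
                "gene_ids": self.gene_ids}
        np.savez(path, __meta__=json.dumps(meta),
                 **{f"param/{k}": v for k, v in self.params.items()})

    @classmethod
    def load(cls, path, expected_gene_ids: Sequence[str] | None = None) -> "SigGCNModel":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["__meta__"]))
            cfg_d = meta["config"]
            cfg_d["nn_hidden_dims"] = tuple(cfg_d["nn_hidden_dims"])
            config = ModelConfig(**cfg_d)
            model = cls(config, meta["classes"], meta["gene_ids"])
            for k in model.params:
                model.params[k] = np.asarray(archive[f"param/{k}"])
        if expected_gene_ids is not None and model.gene_ids is not None:
            if list(expected_gene_ids) != model.gene_ids:
                raise ValueError("checkpoint gene order does not match the provided graph")
        return model


# ---------------------------------------------------------------------------
# Loss primitives (module-level so they are testable in isolation)
# ---------------------------------------------------------------------------

def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def reconstruction_loss(x_batch: np.ndarray, x_hat: np.ndarray) -> float:
    """Per-cell sum of squared errors over genes, averaged over the batch."""
    x_batch = np.atleast_2d(x_batch)
    x_hat = np.atleast_2d(x_hat)
    if x_batch.shape != x_hat.shape:
        raise ValueError("x and x_hat shapes differ")
    return float(np.sum((x_batch - x_hat) ** 2) / x_batch.shape[0])


def classification_loss(probabilities: np.ndarray, true_labels: np.ndarray) -> float:
    """Mean negative log-likelihood of the true class, probabilities clipped."""
    probabilities = np.atleast_2d(probabilities)
    true_labels = np.asarray(true_labels, dtype=np.int64)
    if len(true_labels) != probabilities.shape[0]:
        raise ValueError("label count does not match probability rows")
    picked = probabilities[np.arange(len(true_labels)), true_labels]
    return float(-np.mean(np.log(np.clip(picked, PROB_FLOOR, None))))


def total_loss(l_cla: float, l_rec: float, l_reg: float,
               lambda_cla: float = 1.0, lambda_rec: float = 1.0,
               lambda_reg: float = 1e-4) -> float:
    return lambda_cla * l_cla + lambda_rec * l_rec + lambda_reg * l_reg


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------

@dataclass
class TrainHistory:
    """Per-epoch averaged training losses and validation metrics."""

    epoch: list[int] = field(default_factory=list)
    l_cla: list[float] = field(default_factory=list)
    l_rec: list[float] = field(default_factory=list)
    l_reg: list[float] = field(default_factory=list)
    total: list[float] = field(default_factory=list)
    val_total: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(asdict(self)).to_csv(path, index=False)


def _encode_labels(labels: np.ndarray, classes: Sequence[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    try:
        return np.array([index[str(lab)] for lab in labels], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} not in the training vocabulary") from None


def train(data_train, data_val, lap: ScaledLaplacian | None, config: ModelConfig,
          classes: Sequence[str] | None = None):
    """Mini-batch SGD with momentum on the composite loss, fixed epoch budget.

    ``data_train`` / ``data_val`` are LabeledExpressionMatrix instances sharing
    the graph's gene order.  Initialization and per-epoch shuffling are seeded;
    given a fixed seed and thread count the run is deterministic.  Returns
    (model, TrainHistory); no early stopping — validation metrics are recorded
    for monitoring and tuning only.
    """
    if classes is None:
        classes = sorted(set(data_train.labels))
    classes = [str(c) for c in classes]
    observed = set(map(str, data_train.labels))
    missing = [c for c in classes if c not in observed]
    if missing:
        raise ValueError(f"class {missing[0]!r} absent from training data")
    if config.gcn_enabled:
        if lap is None:
            raise ValueError("a ScaledLaplacian is required when the GCN branch is enabled")
        if lap.n_nodes != data_train.n_genes:
            raise ValueError("graph and expression gene counts differ")

    cfg = config
    if cfg.n_classes != len(classes):
        from dataclasses import replace as _replace
        cfg = _replace(cfg, n_classes=len(classes))
    if cfg.n_genes != data_train.n_genes:
        from dataclasses import replace as _replace
        cfg = _replace(cfg, n_genes=data_train.n_genes)

    model = SigGCNModel(cfg, classes, gene_ids=list(data_train.gene_ids))
    x_tr = np.asarray(data_train.values, dtype=float)
    y_tr = _encode_labels(data_train.labels, classes)
    x_va = np.asarray(data_val.values, dtype=float)
    y_va = _encode_labels(data_val.labels, classes)

    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x5F3)))
    velocity = {k: np.zeros_like(v) for k, v in model.params.items()}
    history = TrainHistory()

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x_tr))
        sums = {"total": 0.0, "cla": 0.0, "rec": 0.0, "reg": 0.0}
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            losses, grads = model.loss_and_grads(lap, x_tr[idx], y_tr[idx])
            for k, g in grads.items():
                velocity[k] = cfg.momentum * velocity[k] + g
                model.params[k] -= cfg.learning_rate * velocity[k]
            for k in sums:
                sums[k] += losses[k]
            n_batches += 1
        probs_va = model.forward(lap, x_va)
        val_cla = classification_loss(probs_va, y_va)
        if cfg.gcn_enabled:
            th1, _ = model.gcn_forward(lap, x_va)
            val_rec = reconstruction_loss(x_va, model.decode(th1))
        else:
            val_rec = 0.0
        val_tot = total_loss(val_cla, val_rec, model.regularization_loss(),
                             cfg.lambda_cla, cfg.lambda_rec, cfg.lambda_reg)
        history.epoch.append(epoch)
        for k, attr in (("cla", "l_cla"), ("rec", "l_rec"), ("reg", "l_reg"),
                        ("total", "total")):
            getattr(history, attr).append(sums[k] / max(n_batches, 1))
        history.val_total.append(val_tot)
        history.val_accuracy.append(float(np.mean(probs_va.argmax(axis=1) == y_va)))
    return model, history


def predict(model: SigGCNModel, lap: ScaledLaplacian | None, data,
            reject_threshold: float | None = None) -> PredictionResult:
    """Forward pass with the optional rejection rule: a cell whose top
    probability is below the threshold is flagged unassigned (its argmax
    label is still reported alongside the flag)."""
    if reject_threshold is None:
        reject_threshold = model.config.reject_threshold
    x = np.asarray(data.values, dtype=float)
    probs = model.forward(lap, x)
    arg = probs.argmax(axis=1)
    labels = np.array([model.classes[i] for i in arg], dtype=object)
    if reject_threshold is not None:
        mask = probs.max(axis=1) < reject_threshold
    else:
        mask = np.zeros(len(arg), dtype=bool)
    return PredictionResult(probabilities=probs, predicted_labels=labels,
                            unassigned_mask=mask, classes=list(model.classes),
                            cell_ids=list(data.cell_ids))
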