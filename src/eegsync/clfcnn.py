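"""Cross-layer fully connected classifier.

Every earlier layer feeds every later layer through its own dense weight +
bias edge; each edge's contribution is rectified and the contributions are
summed (the implicit merge carries fixed weight 1 and bias 0, so it holds no
trainable parameters).  Training is plain mini-batch gradient descent with
momentum and weight decay, mean-squared-error loss on 0/1 labels, inverted
input dropout, and early stopping on training accuracy.

Implemented directly in numpy: the architecture is non-standard (per-edge
rectification, cross-layer summation) and the update rule is prescribed
exactly, so a framework would obscure rather than help.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from eegsync.evaluation import MetricsReport, confusion, metrics, roc_auc

__all__ = [
    "CLFCNNConfig",
    "CLFCNNParams",
    "OptimizerState",
    "TrainHistory",
    "CrossValidationResult",
    "build_model",
    "forward",
    "loss_and_gradients",
    "sgd_momentum_step",
    "fit",
    "predict",
    "split_and_crossvalidate",
]


@dataclass(frozen=True)
class CLFCNNConfig:
    input_dim: int = 529
    hidden_widths: tuple = (80, 20)
    output_dim: int = 1
    dropout_input: float = 0.1
    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 2e-4
    batch_size: int = 50
    max_epochs: int = 300
    patience: int = 1
    threshold: float = 0.5
    seed: int = 0
    cross_layer: bool = True  # False: adjacent-layer edges only (ablation)

    def __post_init__(self) -> None:
        widths = self.widths
        if any(w < 1 for w in widths):
            raise ValueError("all layer widths must be positive")
        if not 0.0 <= self.dropout_input < 1.0:
            raise ValueError("dropout_input must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1 or self.patience < 1:
            raise ValueError("batch_size, max_epochs, patience must be >= 1")

    @property
    def widths(self) -> tuple:
        return (self.input_dim, *self.hidden_widths, self.output_dim)

    @property
    def edges(self) -> list:
        """Forward edges (j, i) with j < i over the layer sequence."""
        n_layers = len(self.widths)
        if self.cross_layer:
            return [(j, i) for i in range(1, n_layers) for j in range(i)]
        return [(i - 1, i) for i in range(1, n_layers)]


@dataclass
class CLFCNNParams:
    """Per-edge weight matrices and bias vectors, keyed by (source, target)."""

    widths: tuple
    weights: dict = field(default_factory=dict)  # (j, i) -> (w_j, w_i) array
    biases: dict = field(default_factory=dict)  # (j, i) -> (w_i,) array

    @property
    def edges(self) -> list:
        return sorted(self.weights.keys())

    def edge_param_count(self, edge: tuple) -> int:
        return self.weights[edge].size + self.biases[edge].size

    @property
    def param_count(self) -> int:
        return sum(self.edge_param_count(e) for e in self.edges)

    def copy(self) -> "CLFCNNParams":
        return CLFCNNParams(
            widths=self.widths,
            weights={e: w.copy() for e, w in self.weights.items()},
            biases={e: b.copy() for e, b in self.biases.items()},
        )


@dataclass
class OptimizerState:
    """Momentum buffers mirroring every parameter tensor."""

    velocity_w: dict
    velocity_b: dict
    iteration: int = 0

    @classmethod
    def zeros_like(cls, params: CLFCNNParams) -> "OptimizerState":
        return cls(
            velocity_w={e: np.zeros_like(w) for e, w in params.weights.items()},
            velocity_b={e: np.zeros_like(b) for e, b in params.biases.items()},
        )


@dataclass
class TrainHistory:
    acc: list = field(default_factory=list)
    loss: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.acc)


def build_model(config: CLFCNNConfig, seed: Union[int, None] = None) -> CLFCNNParams:
    """Initialize one weight+bias block per forward edge.

    Weights are uniform in +/- sqrt(6 / (fan_in + fan_out)); biases start at
    zero.  With the default topology (529 -> 80 -> 20 -> 1, all cross edges)
    the model holds 55,252 trainable parameters.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    widths = config.widths
    params = CLFCNNParams(widths=widths)
    for j, i in config.edges:
        fan_in, fan_out = widths[j], widths[i]
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        params.weights[(j, i)] = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        params.biases[(j, i)] = np.zeros(fan_out)
    return params


def _forward_pass(
    params: CLFCNNParams,
    X: np.ndarray,
    config: CLFCNNConfig,
    training: bool,
    rng: Union[np.random.Generator, None],
) -> tuple:
    """Activations and per-edge pre-activations for a batch (rows = samples)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.widths[0]:
        raise ValueError(
            f"feature dim {X.shape[1]} != input width {params.widths[0]}"
        )
    a0 = X
    if training and config.dropout_input > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        keep = 1.0 - config.dropout_input
        mask = (rng.random(X.shape) < keep) / keep  # inverted dropout
        a0 = X * mask
    activations = [a0] + [None] * (len(params.widths) - 1)
    pre = {}
    for j, i in params.edges:
        z = activations[j] @ params.weights[(j, i)] + params.biases[(j, i)]
        pre[(j, i)] = z
        contrib = np.maximum(z, 0.0)  # per-edge rectification
        if activations[i] is None:
            activations[i] = contrib
        else:
            activations[i] = activations[i] + contrib
    return activations, pre


def forward(
    params: CLFCNNParams,
    features: np.ndarray,
    config: CLFCNNConfig = CLFCNNConfig(),
    training: bool = False,
    rng: Union[np.random.Generator, None] = None,
) -> np.ndarray:
    """Scalar output per sample (non-negative: a sum of rectified terms).

    The outer rectification of the output layer is the identity here because
    each edge contribution is already rectified before summation.
    """
    activations, _ = _forward_pass(params, features, config, training, rng)
    return activations[-1][:, 0]


def loss_and_gradients(
    params: CLFCNNParams,
    features: np.ndarray,
    labels: np.ndarray,
    config: CLFCNNConfig = CLFCNNConfig(),
    training: bool = False,
    rng: Union[np.random.Generator, None] = None,
) -> tuple:
    """Mean-squared-error loss and its gradients for one batch.

    Reverse-mode chain rule over every cross-layer edge; gradients are
    averaged over the batch (matching the loss).  Returns
    ``(loss, grads_w, grads_b)`` with the two dicts keyed like the params.
    """
    y = np.asarray(labels, dtype=float).reshape(-1)
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    if X.shape[0] != y.size:
        raise ValueError("features and labels must have equal length")

    activations, pre = _forward_pass(params, X, config, training, rng)
    out = activations[-1][:, 0]
    resid = out - y
    loss = float(np.mean(resid**2))

    n_layers = len(params.widths)
    grad_a = [None] * n_layers
    grad_a[n_layers - 1] = (2.0 * resid / y.size)[:, None]
    grads_w, grads_b = {}, {}
    for j, i in sorted(params.edges, reverse=True):
        gz = grad_a[i] * (pre[(j, i)] > 0)  # rectifier gate
        grads_w[(j, i)] = activations[j].T @ gz
        grads_b[(j, i)] = gz.sum(axis=0)
        back = gz @ params.weights[(j, i)].T
        grad_a[j] = back if grad_a[j] is None else grad_a[j] + back
    return loss, grads_w, grads_b


def sgd_momentum_step(
    params: CLFCNNParams,
    state: OptimizerState,
    grads_w: dict,
    grads_b: dict,
    config: CLFCNNConfig,
) -> None:
    """In-place momentum update with weight decay, applied element-wise:

        v <- momentum * v - weight_decay * lr * w - lr * grad
        w <- w + v
    """
    lr, mom, wd = config.learning_rate, config.momentum, config.weight_decay
    for e in params.edges:
        vw = state.velocity_w[e]
        vw *= mom
        vw -= wd * lr * params.weights[e] + lr * grads_w[e]
        params.weights[e] += vw
        vb = state.velocity_b[e]
        vb *= mom
        vb -= wd * lr * params.biases[e] + lr * grads_b[e]
        params.biases[e] += vb
    state.iteration += 1


def _accuracy_and_loss(
    params: CLFCNNParams, X: np.ndarray, y: np.ndarray, config: CLFCNNConfig
) -> tuple:
    out = forward(params, X, config, training=False)
    loss = float(np.mean((out - y) ** 2))
    acc = float(np.mean((out >= config.threshold) == (y >= 0.5)))
    return acc, loss


def fit(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    val_features: Union[np.ndarray, None] = None,
    val_labels: Union[np.ndarray, None] = None,
    config: CLFCNNConfig = CLFCNNConfig(),
) -> tuple:
    """Train a fresh model; returns ``(params, TrainHistory)``.

    Mini-batches are reshuffled each epoch (seeded).  Training stops when
    training accuracy has not increased for ``config.patience`` consecutive
    epochs, or at ``config.max_epochs``.
    """
    X = np.atleast_2d(np.asarray(train_features, dtype=float))
    y = np.asarray(train_labels, dtype=float).reshape(-1)
    if X.shape[0] < 1:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    params = build_model(config, seed=config.seed)
    state = OptimizerState.zeros_like(params)
    history = TrainHistory()

    best_acc = -np.inf
    stall = 0
    for _epoch in range(config.max_epochs):
        order = rng.permutation(X.shape[0])
        for lo in range(0, X.shape[0], config.batch_size):
            sel = order[lo : lo + config.batch_size]
            _, gw, gb = loss_and_gradients(
                params, X[sel], y[sel], config, training=True, rng=rng
            )
            sgd_momentum_step(params, state, gw, gb, config)
        acc, loss = _accuracy_and_loss(params, X, y, config)
        history.acc.append(acc)
        history.loss.append(loss)
        if val_features is not None and len(val_features):
            vacc, vloss = _accuracy_and_loss(
                params, np.atleast_2d(val_features),
                np.asarray(val_labels, dtype=float).reshape(-1), config,
            )
            history.val_acc.append(vacc)
            history.val_loss.append(vloss)
        if acc > best_acc:
            best_acc = acc
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    return params, history


def predict(
    params: CLFCNNParams,
    features: np.ndarray,
    config: CLFCNNConfig = CLFCNNConfig(),
    threshold: Union[float, None] = None,
) -> np.ndarray:
    """Binary labels: 1 (seizure) iff the output reaches the threshold."""
    thr = config.threshold if threshold is None else threshold
    return (forward(params, features, config, training=False) >= thr).astype(int)


@dataclass
class CrossValidationResult:
    fold_metrics: list
    test_metrics: MetricsReport
    test_confusion: object
    params: CLFCNNParams
    history: TrainHistory
    split_indices: dict


def _evaluate_split(
    params: CLFCNNParams,
    X: np.ndarray,
    y: np.ndarray,
    config: CLFCNNConfig,
) -> tuple:
    preds = predict(params, X, config)
    counts = confusion(y.astype(int), preds)
    report = metrics(counts)
    if len(np.unique(y)) < 2:
        warnings.warn("a class is absent from this evaluation split; "
                      "AUC undefined", stacklevel=2)
    else:
        report.auc = roc_auc(forward(params, X, config), y.astype(int))
    return report, counts


def split_and_crossvalidate(
    features: np.ndarray,
    labels: np.ndarray,
    config: CLFCNNConfig = CLFCNNConfig(),
    n_folds: int = 5,
    split_seed: int = 7,
) -> CrossValidationResult:
    """Seeded shuffle, 64/16/20 train/validation/test split, k-fold rotation
    over the train+validation pool, and a final model retrained on the full
    pool scored on the held-out test set."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=float).reshape(-1)
    n = X.shape[0]
    if n < n_folds:
        raise ValueError("dataset smaller than fold count")
    order = np.random.default_rng(split_seed).permutation(n)
    n_train = int(n * 0.64)
    n_val = int(n * 0.16)
    pool = order[: n_train + n_val]
    test = order[n_train + n_val :]

    fold_metrics = []
    fold_ids = np.arange(pool.size) % n_folds
    for f in range(n_folds):
        tr, va = pool[fold_ids != f], pool[fold_ids == f]
        fold_params, _ = fit(X[tr], y[tr], X[va], y[va], config)
        report, _ = _evaluate_split(fold_params, X[va], y[va], config)
        fold_metrics.append(report)

    final_params, history = fit(X[pool], y[pool], X[test], y[test], config)
    test_report, test_counts = _evaluate_split(final_params, X[test], y[test], config)
    return CrossValidationResult(
        fold_metrics=fold_metrics,
        test_metrics=test_report,
        test_confusion=test_counts,
        params=final_params,
        history=history,
        split_indices={"pool": pool, "test": test},
    )
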