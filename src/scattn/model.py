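"""Attention-based graph neural network for transductive node classification.

Architecture: a linear input layer with ReLU, T attention-propagation
layers, and a linear output layer with softmax. Each propagation layer
replaces a node's embedding with a convex combination of its neighbourhood
(including itself), weighted by softmax(beta * cosine similarity) where
beta is a learned per-layer scalar. Training is full-batch transductive:
the forward pass covers the whole reference+query graph while the
negative-log-likelihood loss is evaluated on the labelled training nodes
only.

The entire forward/backward pass is implemented in NumPy with analytic
gradients (including the gradient of the attention weights with respect to
the node embeddings and beta), optimised with Adam under a step learning
rate schedule and early stopping on validation accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .graph import EdgeList

logger = logging.getLogger(__name__)

_EPS_NORM = 1e-12
_EPS_LOG = 1e-12


@dataclass
class AGNNModel:
    """Parameters of the attention graph network.

    W0 maps input features (m genes) to H hidden units; ``betas`` holds the
    per-propagation-layer attention temperatures (the first is initialised
    at 1, the rest uniformly in (0, 1); all are trainable); W1 maps hidden
    units to the L class logits.
    """

    W0: np.ndarray
    betas: np.ndarray
    W1: np.ndarray

    @property
    def n_hidden(self) -> int:
        return self.W0.shape[1]

    @property
    def n_layers(self) -> int:
        return self.betas.size

    @property
    def n_classes(self) -> int:
        return self.W1.shape[1]

    @property
    def n_parameters(self) -> int:
        return self.W0.size + self.betas.size + self.W1.size

    def copy(self) -> "AGNNModel":
        return AGNNModel(self.W0.copy(), self.betas.copy(), self.W1.copy())


def init_model(
    n_features: int, n_hidden: int, n_layers: int, n_classes: int, seed: int = 0
) -> AGNNModel:
    """Symmetric-uniform fan-in initialisation; first beta fixed at 1,
    remaining betas Uniform(0, 1)."""
    if n_layers < 1:
        raise ValueError("need at least one attention layer")
    rng = np.random.default_rng(seed)
    b0 = 1.0 / np.sqrt(n_features)
    b1 = 1.0 / np.sqrt(n_hidden)
    W0 = rng.uniform(-b0, b0, size=(n_features, n_hidden))
    W1 = rng.uniform(-b1, b1, size=(n_hidden, n_classes))
    betas = np.concatenate([[1.0], rng.uniform(0.0, 1.0, size=n_layers - 1)])
    return AGNNModel(W0=W0, betas=betas, W1=W1)


def _edge_arrays(edges: EdgeList) -> tuple[np.ndarray, np.ndarray]:
    """Directed edge arrays (src, dst) with a self-loop appended per node."""
    loops = np.arange(edges.n_nodes, dtype=np.int64)
    if edges.n_edges:
        src = np.concatenate([edges.edges[:, 0], loops])
        dst = np.concatenate([edges.edges[:, 1], loops])
    else:
        src = dst = loops
    return src, dst


def _attention_layer_forward(H, src, dst, beta):
    """One propagation step: returns (output, cache for backward).

    Attention over N(i) u {i}: P_ij = softmax_j(beta * cos(h_i, h_j)).
    Zero-norm embeddings get cosine 0 (epsilon guard).
    """
    n = H.shape[0]
    norms = np.linalg.norm(H, axis=1)
    safe = norms > _EPS_NORM
    denom = norms[src] * norms[dst]
    valid = safe[src] & safe[dst]
    dots = np.einsum("ij,ij->i", H[src], H[dst])
    c = np.where(valid, dots / np.where(valid, denom, 1.0), 0.0)

    s = beta * c
    rowmax = np.full(n, -np.inf)
    np.maximum.at(rowmax, src, s)
    e = np.exp(s - rowmax[src])
    rowsum = np.bincount(src, weights=e, minlength=n)
    P = e / rowsum[src]

    out = sparse.coo_matrix((P, (src, dst)), shape=(n, n)) @ H
    cache = dict(H=H, P=P, c=c, norms=norms, valid=valid, denom=denom, beta=beta)
    return out, cache


def _attention_layer_backward(G, src, dst, cache):
    """Backprop through one attention layer.

    Returns (dH, dbeta): gradient wrt the layer input embeddings and wrt
    the attention temperature. G is the gradient wrt the layer output.
    """
    H, P, c = cache["H"], cache["P"], cache["c"]
    norms, valid, denom, beta = cache["norms"], cache["valid"], cache["denom"], cache["beta"]
    n = H.shape[0]

    # direct path: out_i = sum_j P_ij h_j
    dH = sparse.coo_matrix((P, (src, dst)), shape=(n, n)).T @ G

    # through the softmax weights
    g = np.einsum("ij,ij->i", G[src], H[dst])  # dL/dP per edge
    rowdot = np.bincount(src, weights=P * g, minlength=n)
    u = P * (g - rowdot[src])  # dL/ds per edge
    dbeta = float(np.sum(u * c))

    # through the cosine similarities (zero where the epsilon guard fired)
    dc = np.where(valid, beta * u, 0.0)
    safe_denom = np.where(valid, denom, 1.0)
    w = dc / safe_denom
    dH += sparse.coo_matrix((w, (src, dst)), shape=(n, n)) @ H  # d cos / d h_src part 1
    dH += sparse.coo_matrix((w, (dst, src)), shape=(n, n)) @ H  # d cos / d h_dst part 1
    sq_src = np.where(valid, norms[src] ** 2, 1.0)
    sq_dst = np.where(valid, norms[dst] ** 2, 1.0)
    coef_src = np.bincount(src, weights=dc * c / sq_src, minlength=n)
    coef_dst = np.bincount(dst, weights=dc * c / sq_dst, minlength=n)
    dH -= (coef_src + coef_dst)[:, None] * H
    return dH, dbeta


def attention_weights(h: np.ndarray, edges: EdgeList, beta: float) -> sparse.csr_matrix:
    """Row-stochastic attention matrix over N(i) u {i} (self-loops included)."""
    h = np.asarray(h, dtype=float)
    src, dst = _edge_arrays(edges)
    n = edges.n_nodes
    norms = np.linalg.norm(h, axis=1)
    safe = norms > _EPS_NORM
    valid = safe[src] & safe[dst]
    denom = np.where(valid, norms[src] * norms[dst], 1.0)
    c = np.where(valid, np.einsum("ij,ij->i", h[src], h[dst]) / denom, 0.0)
    s = beta * c
    rowmax = np.full(n, -np.inf)
    np.maximum.at(rowmax, src, s)
    e = np.exp(s - rowmax[src])
    rowsum = np.bincount(src, weights=e, minlength=n)
    P = e / rowsum[src]
    return sparse.csr_matrix((P, (src, dst)), shape=(n, n))


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=1, keepdims=True)


def forward(
    model: AGNNModel, F_norm: np.ndarray, edges: EdgeList, return_cache: bool = False
):
    """Full forward pass: node x class probability matrix (rows sum to 1)."""
    F_norm = np.asarray(F_norm, dtype=float)
    if F_norm.shape[1] != model.W0.shape[0]:
        raise ValueError(
            f"feature dimension {F_norm.shape[1]} does not match W0 rows "
            f"{model.W0.shape[0]}"
        )
    src, dst = _edge_arrays(edges)
    Z0 = F_norm @ model.W0
    H = np.maximum(Z0, 0.0)
    caches = []
    for beta in model.betas:
        H, cache = _attention_layer_forward(H, src, dst, float(beta))
        caches.append(cache)
    logits = H @ model.W1
    probs = _softmax(logits)
    if return_cache:
        return probs, dict(src=src, dst=dst, Z0=Z0, H_final=H, caches=caches, F=F_norm)
    return probs


def nll_loss(probabilities: np.ndarray, labels: np.ndarray, node_subset: np.ndarray) -> float:
    """Mean negative log-likelihood of the true classes over a node subset."""
    node_subset = np.asarray(node_subset)
    if node_subset.size == 0:
        raise ValueError("node subset is empty")
    p = probabilities[node_subset, labels[node_subset]]
    return float(-np.mean(np.log(np.maximum(p, _EPS_LOG))))


def _loss_and_gradients(model, F_norm, edges_arrays, labels, train_idx):
    """One combined forward/backward pass; returns loss, probs and grads."""
    src, dst = edges_arrays
    Z0 = F_norm @ model.W0
    H = np.maximum(Z0, 0.0)
    caches = []
    for beta in model.betas:
        H, cache = _attention_layer_forward(H, src, dst, float(beta))
        caches.append(cache)
    logits = H @ model.W1
    probs = _softmax(logits)
    loss = nll_loss(probs, labels, train_idx)

    n_train = train_idx.size
    dZ = np.zeros_like(probs)
    dZ[train_idx] = probs[train_idx]
    dZ[train_idx, labels[train_idx]] -= 1.0
    dZ /= n_train

    dW1 = H.T @ dZ
    G = dZ @ model.W1.T
    dbetas = np.zeros_like(model.betas)
    for t in range(len(caches) - 1, -1, -1):
        G, db = _attention_layer_backward(G, src, dst, caches[t])
        dbetas[t] = db
    G = G * (Z0 > 0)  # ReLU
    dW0 = F_norm.T @ G
    return loss, probs, dict(W0=dW0, betas=dbetas, W1=dW1)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters.

    The learning rate follows a step schedule lr = learning_rate *
    gamma ** floor(epoch / step_size); training stops when validation
    accuracy has not improved for ``patience`` epochs.
    """

    learning_rate: float = 0.01
    step_size: int = 10
    gamma: float = 0.8
    patience: int = 2000
    max_epochs: int = 10000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must be in (0, 1]")
        if self.patience < 1 or self.step_size < 1 or self.max_epochs < 1:
            raise ValueError("patience, step_size and max_epochs must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch training trace."""

    loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_early: bool = False

    @property
    def n_epochs(self) -> int:
        return len(self.loss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(self.n_epochs),
                "loss": self.loss,
                "val_accuracy": self.val_accuracy,
                "learning_rate": self.learning_rate,
            }
        )


def learning_rate_at(epoch: int, cfg: TrainConfig) -> float:
    """Step schedule: lr0 * gamma ** floor(epoch / step_size)."""
    return cfg.learning_rate * cfg.gamma ** (epoch // cfg.step_size)


def _validation_accuracy(probs: np.ndarray, labels: np.ndarray, val_idx: np.ndarray) -> float:
    pred = np.argmax(probs[val_idx], axis=1)
    return float(np.mean(pred == labels[val_idx]))


class _Adam:
    def __init__(self, shapes, b1=0.9, b2=0.999, eps=1e-8):
        self.b1, self.b2, self.eps = b1, b2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, params: dict, grads: dict, lr: float) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


def train(
    model: AGNNModel,
    F_norm: np.ndarray,
    edges: EdgeList,
    labels: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    cfg: TrainConfig = TrainConfig(),
) -> tuple[AGNNModel, TrainHistory]:
    """Full-batch transductive training with Adam and early stopping.

    ``labels`` is a per-node integer class vector (entries outside
    ``train_idx``/``val_idx`` may be arbitrary). Returns the parameters of
    the best-validation epoch and the per-epoch history.
    """
    F_norm = np.asarray(F_norm, dtype=float)
    labels = np.asarray(labels)
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx)
    if train_idx.size == 0 or val_idx.size == 0:
        raise ValueError("train and validation subsets must be non-empty")

    model = model.copy()
    params = {"W0": model.W0, "betas": model.betas, "W1": model.W1}
    opt = _Adam({k: v.shape for k, v in params.items()})
    edges_arrays = _edge_arrays(edges)

    history = TrainHistory()
    best = model.copy()
    best_acc = -np.inf
    best_epoch = 0
    for epoch in range(cfg.max_epochs):
        lr = learning_rate_at(epoch, cfg)
        loss, probs, grads = _loss_and_gradients(
            model, F_norm, edges_arrays, labels, train_idx
        )
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch}: {loss}"
            )
        val_acc = _validation_accuracy(probs, labels, val_idx)
        history.loss.append(loss)
        history.val_accuracy.append(val_acc)
        history.learning_rate.append(lr)
        if val_acc > best_acc:
            best_acc = val_acc
            best = model.copy()
            best_epoch = epoch
        elif epoch - best_epoch >= cfg.patience:
            history.stopped_early = True
            break
        opt.step(params, grads, lr)
    history.best_epoch = best_epoch
    return best, history


def predict(
    model: AGNNModel,
    F_norm: np.ndarray,
    edges: EdgeList,
    node_subset: np.ndarray | None = None,
) -> np.ndarray:
    """Argmax class per node (ties resolve to the lowest class index)."""
    probs = forward(model, F_norm, edges)
    if node_subset is not None:
        probs = probs[np.asarray(node_subset)]
    return np.argmax(probs, axis=1)


class AGNNClassifier(ClassifierMixin, BaseEstimator):
    """Transductive attention-graph-network classifier (sklearn-style).

    Parameters
    ----------
    n_hidden : int, default=64
        Hidden units of the input linear layer.
    n_layers : int, default=2
        Number of attention propagation layers.
    learning_rate, step_size, gamma, patience, max_epochs
        Optimisation settings, see :class:`TrainConfig`.
    random_state : int, default=0
        Seed for weight initialisation.

    The estimator is transductive: ``fit`` receives the feature matrix of
    *all* nodes (reference and query), the undirected edge list, and the
    indices of labelled training/validation nodes. ``y`` uses the sklearn
    semi-supervised convention: label -1 marks unlabelled nodes.
    """

    def __init__(
        self,
        n_hidden: int = 64,
        n_layers: int = 2,
        learning_rate: float = 0.01,
        step_size: int = 10,
        gamma: float = 0.8,
        patience: int = 2000,
        max_epochs: int = 10000,
        random_state: int = 0,
    ):
        self.n_hidden = n_hidden
        self.n_layers = n_layers
        self.learning_rate = learning_rate
        self.step_size = step_size
        self.gamma = gamma
        self.patience = patience
        self.max_epochs = max_epochs
        self.random_state = random_state

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            step_size=self.step_size,
            gamma=self.gamma,
            patience=self.patience,
            max_epochs=self.max_epochs,
            seed=self.random_state,
        )

    def fit(self, X, y, *, edges: EdgeList, train_idx=None, val_idx=None):
        """Fit on the full transductive graph.

        ``y`` holds one entry per node with -1 for unlabelled nodes. When
        ``train_idx``/``val_idx`` are omitted, labelled nodes are split
        90/10 (seeded) into train and validation.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y must agree on the number of nodes")
        if X.shape[0] != edges.n_nodes:
            raise ValueError("X rows must match the graph's node count")

        labelled = np.flatnonzero(y != -1) if y.dtype.kind in "iu" else np.flatnonzero(
            pd.notna(y) & (y != -1)
        )
        self.classes_ = np.unique(y[labelled])
        class_index = {c: i for i, c in enumerate(self.classes_)}
        y_enc = np.zeros(y.shape[0], dtype=np.int64)
        y_enc[labelled] = [class_index[v] for v in y[labelled]]

        if train_idx is None or val_idx is None:
            rng = np.random.default_rng(self.random_state)
            perm = rng.permutation(labelled)
            n_val = max(1, int(round(0.1 * perm.size)))
            val_idx = perm[:n_val]
            train_idx = perm[n_val:]

        model = init_model(
            X.shape[1],
            self.n_hidden,
            self.n_layers,
            self.classes_.size,
            seed=self.random_state,
        )
        best, history = train(
            model,
            X,
            edges,
            y_enc,
            np.asarray(train_idx),
            np.asarray(val_idx),
            self._train_config(),
        )
        self.model_ = best
        self.history_ = history
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X, *, edges: EdgeList) -> np.ndarray:
        check_is_fitted(self, "model_")
        return forward(self.model_, np.asarray(X, dtype=float), edges)

    def predict(self, X, *, edges: EdgeList) -> np.ndarray:
        idx = np.argmax(self.predict_proba(X, edges=edges), axis=1)
        return self.classes_[idx]


def architecture_search(
    F_norm: np.ndarray,
    edges: EdgeList,
    labels: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    grid_hidden=(32, 64, 128, 256),
    grid_layers=(2, 3, 4, 5),
    cfg: TrainConfig = TrainConfig(),
    trainer=train,
) -> tuple[AGNNModel, pd.DataFrame]:
    """Grid search over hidden width and propagation depth.

    Trains one model per (hidden, layers) combination and returns the one
    with the best validation accuracy (ties resolve to fewer parameters,
    then to grid order) together with the full sweep table.
    """
    if not len(grid_hidden) or not len(grid_layers):
        raise ValueError("grids must be non-empty")
    n_classes = int(np.max(labels[np.concatenate([train_idx, val_idx])])) + 1
    rows = []
    best_model, best_key = None, None
    for H in grid_hidden:
        for T in grid_layers:
            model0 = init_model(F_norm.shape[1], H, T, n_classes, seed=cfg.seed)
            fitted, history = trainer(
                model0, F_norm, edges, labels, train_idx, val_idx, cfg
            )
            val_acc = (
                max(history.val_accuracy) if history.val_accuracy else -np.inf
            )
            rows.append(
                dict(
                    n_hidden=H,
                    n_layers=T,
                    val_accuracy=val_acc,
                    n_parameters=fitted.n_parameters,
                    best_epoch=history.best_epoch,
                    epochs_run=history.n_epochs,
                )
            )
            key = (-val_acc, fitted.n_parameters)
            if best_key is None or key < best_key:
                best_key = key
                best_model = fitted
    table = pd.DataFrame(rows)
    return best_model, table
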