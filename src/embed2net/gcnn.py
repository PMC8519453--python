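"""Spectral graph-convolutional classifier with Chebyshev filters.

The classifier follows the spectral construction in which a graph signal x
is filtered by a K-term Chebyshev polynomial in the rescaled normalized
Laplacian,

    y = sum_{k=0}^{K-1} theta_k T_k(L~) x,
    T_0 = I, T_1 = L~, T_k = 2 L~ T_{k-1} - T_{k-2},

which is exactly (K-1)-hop localized. The network stacks two such
convolutional layers (32 filters each, size-2 max pooling after each, on a
coarsening hierarchy with padded fake vertices), two fully connected layers
(512 and 128 units) and a 2-class softmax. Training is plain mini-batch
Adam on cross-entropy with dropout on the fully connected layers; forward
and backward passes are written directly in numpy so runs are deterministic
for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import coarsening
from .errors import ParameterError, StructureError, TrainingError
from .expression import GraphAlignedDataset
from .networks import SimilarityNetwork


@dataclass(frozen=True)
class GCNNArchitecture:
    filters: tuple[int, int] = (32, 32)
    cheb_order: int = 7
    pool: tuple[int, int] = (2, 2)
    fc: tuple[int, int] = (512, 128)
    n_classes: int = 2

    def __post_init__(self):
        if self.cheb_order < 1:
            raise ParameterError("Chebyshev order must be >= 1")
        if any(w <= 0 for w in self.fc):
            raise ParameterError("fully connected widths must be positive")
        if any(p != 2 for p in self.pool):
            raise ParameterError("only size-2 pooling is supported")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    folds: int = 10
    seed: int = 0
    learning_rate: float = 1e-3
    batch_size: int = 32
    dropout: float = 0.5
    weight_decay: float = 0.0

    def __post_init__(self):
        if self.folds < 2 or self.epochs < 1:
            raise ParameterError("need folds >= 2 and epochs >= 1")


@dataclass
class GraphOperator:
    """Laplacians, permutations and fake-vertex masks per coarsening level."""
    laplacians: list[sp.csr_matrix]
    perms: list[list[int]]
    masks: list[np.ndarray]       # True for real vertices, per level
    vertex_order: list[str]

    @property
    def n_input(self) -> int:
        return len(self.perms[0])


@dataclass
class EvaluationResult:
    fold_metrics: pd.DataFrame    # folds x {auc, accuracy, f1_weighted}
    converged: list[bool] = field(default_factory=list)

    @property
    def mean(self) -> pd.Series:
        return self.fold_metrics.mean(axis=0)

    @property
    def sem(self) -> pd.Series:
        n = len(self.fold_metrics)
        return self.fold_metrics.std(axis=0, ddof=1) / np.sqrt(n)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sem": self.sem})


def build_graph_operator(network: SimilarityNetwork,
                         levels: int = 2) -> GraphOperator:
    """Coarsening hierarchy + rescaled Laplacians for a connected graph."""
    if network.n_vertices == 0 or not nx.is_connected(network.graph):
        raise StructureError(
            "graph operator needs a connected graph; extract the main "
            "component first")
    order = network.vertices
    A = sp.csr_matrix(np.abs(network.adjacency(order)))
    graphs = [A]
    parents = []
    for _ in range(levels):
        parent = coarsening.heavy_edge_matching(graphs[-1])
        parents.append(parent)
        graphs.append(coarsening.coarsen_graph(graphs[-1], parent))
    perms = coarsening.compute_perm(parents)
    laplacians, masks = [], []
    for lvl in range(levels + 1):
        n_real = graphs[lvl].shape[0]
        A_perm = coarsening.perm_adjacency(graphs[lvl], perms[lvl])
        laplacians.append(coarsening.rescaled_laplacian(A_perm))
        masks.append(np.array([i < n_real for i in perms[lvl]]))
    return GraphOperator(laplacians, perms, masks, order)


# -- Chebyshev filtering ---------------------------------------------------

def _cheb_basis(L: sp.spmatrix, X: np.ndarray, K: int) -> np.ndarray:
    """Stack [T_0 X, ..., T_{K-1} X]; X is (B, N, F) -> (K, B, N, F)."""
    B, N, F = X.shape
    x0 = np.ascontiguousarray(X.transpose(1, 0, 2)).reshape(N, B * F)
    terms = [x0]
    if K > 1:
        terms.append(L @ x0)
    for _ in range(2, K):
        terms.append(2 * (L @ terms[-1]) - terms[-2])
    stack = np.stack([t.reshape(N, B, F).transpose(1, 0, 2) for t in terms])
    return stack


def _cheb_apply(L: sp.spmatrix, Z: np.ndarray, k: int) -> np.ndarray:
    """Apply T_k(L) to Z of shape (B, N, F)."""
    B, N, F = Z.shape
    z0 = np.ascontiguousarray(Z.transpose(1, 0, 2)).reshape(N, B * F)
    if k == 0:
        out = z0
    elif k == 1:
        out = L @ z0
    else:
        prev, cur = z0, L @ z0
        for _ in range(2, k + 1):
            prev, cur = cur, 2 * (L @ cur) - prev
        out = cur
    return out.reshape(N, B, F).transpose(1, 0, 2)


def _cheb_adjoint_sum(L: sp.spmatrix, Z: np.ndarray) -> np.ndarray:
    """Compute sum_k T_k(L) Z[k] by a Clenshaw-style reverse recurrence.

    Z has shape (K, B, N, F); T_k is symmetric, so this is the adjoint of
    the basis expansion in K sparse products instead of O(K^2).
    """
    K, B, N, F = Z.shape
    zmat = np.ascontiguousarray(Z.transpose(0, 2, 1, 3)).reshape(K, N, B * F)
    b_next = np.zeros((N, B * F), dtype=Z.dtype)
    b_after = np.zeros_like(b_next)
    for k in range(K - 1, 0, -1):
        b_next, b_after = zmat[k] + 2 * (L @ b_next) - b_after, b_next
    out = zmat[0] + L @ b_next - b_after
    return out.reshape(N, B, F).transpose(1, 0, 2)


def chebyshev_conv(features: np.ndarray,
                   operator: GraphOperator | sp.spmatrix | np.ndarray,
                   K: int, weights: np.ndarray) -> np.ndarray:
    """Filter per-vertex signals: sum_k theta_k T_k(L~) x.

    `features` may be (N,), (N, F) or (B, N, F); `weights` is (K,) for
    scalar filters or (K, F_in, F_out) for filter banks.
    """
    L = operator.laplacians[0] if isinstance(operator, GraphOperator) \
        else sp.csr_matrix(operator)
    x = np.asarray(features, dtype=float)
    squeeze = []
    if x.ndim == 1:
        x = x[None, :, None]
        squeeze = [0, -1]
    elif x.ndim == 2:
        x = x[None, :, :]
        squeeze = [0]
    theta = np.asarray(weights, dtype=float)
    if theta.ndim == 1:
        theta = theta[:, None, None] * np.eye(x.shape[2])[None]
    if theta.shape[0] != K:
        raise ParameterError(
            f"weights first dimension {theta.shape[0]} != order {K}")
    basis = _cheb_basis(L, x, K)
    out = np.einsum("kbnf,kfg->bng", basis, theta)
    for ax in sorted(squeeze, reverse=True):
        out = np.squeeze(out, axis=ax)
    return out


# -- the network -----------------------------------------------------------

def _maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    B, N, F = x.shape
    xr = x.reshape(B, N // 2, 2, F)
    arg = xr.argmax(axis=2)
    return xr.max(axis=2), arg


def _maxpool2_backward(grad: np.ndarray, arg: np.ndarray,
                       n: int) -> np.ndarray:
    B, half, F = grad.shape
    out = np.zeros((B, half, 2, F), dtype=grad.dtype)
    np.put_along_axis(out, arg[:, :, None, :], grad[:, :, None, :], axis=2)
    return out.reshape(B, n, F)


class GraphConvNet:
    """Two Chebyshev convolution blocks + two fully connected layers."""

    def __init__(self, operator: GraphOperator, arch: GCNNArchitecture,
                 seed: int = 0):
        self.operator = operator
        self.arch = arch
        self.rng = np.random.default_rng(seed)
        K = arch.cheb_order
        f1, f2 = arch.filters
        n0 = len(operator.perms[0])
        if n0 % 2 or len(operator.perms[1]) % 2:
            raise ParameterError("padded vertex counts must be even")
        n2 = len(operator.perms[2])
        self.flat_dim = n2 * f2

        def he(shape, fan_in):
            return self.rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                   size=shape).astype(np.float32)

        self.params = {
            "theta1": he((K, 1, f1), K),
            "b1": np.zeros(f1, dtype=np.float32),
            "theta2": he((K, f1, f2), K * f1),
            "b2": np.zeros(f2, dtype=np.float32),
            "W1": he((self.flat_dim, arch.fc[0]), self.flat_dim),
            "c1": np.zeros(arch.fc[0], dtype=np.float32),
            "W2": he((arch.fc[0], arch.fc[1]), arch.fc[0]),
            "c2": np.zeros(arch.fc[1], dtype=np.float32),
            "W3": he((arch.fc[1], arch.n_classes), arch.fc[1]),
            "c3": np.zeros(arch.n_classes, dtype=np.float32),
        }
        self._L32 = [sp.csr_matrix(L, dtype=np.float32)
                     for L in operator.laplacians]
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0
        # input preconditioning: center/scale constants frozen at fit time
        # so the He-scaled initialization sees unit-scale signals
        self._input_loc = 0.0
        self._input_scale = 1.0
        self.loss_history: list[float] = []
        self.converged: bool | None = None

    # forward ------------------------------------------------------------
    @staticmethod
    def _flat_basis(L: sp.spmatrix, X: np.ndarray, K: int) -> np.ndarray:
        """(B, N, K*F) Chebyshev feature expansion, GEMM-ready."""
        basis = _cheb_basis(L, X, K)                      # (K, B, N, F)
        return np.ascontiguousarray(basis.transpose(1, 2, 0, 3)).reshape(
            X.shape[0], X.shape[1], -1)

    @staticmethod
    def _conv(flat_basis: np.ndarray, theta: np.ndarray,
              bias: np.ndarray) -> np.ndarray:
        K, fin, fout = theta.shape
        B, N, _ = flat_basis.shape
        out = flat_basis.reshape(B * N, K * fin) @ theta.reshape(K * fin, fout)
        return out.reshape(B, N, fout) + bias

    def _forward(self, X: np.ndarray, train: bool, dropout: float):
        p = self.params
        op = self.operator
        K = self.arch.cheb_order
        cache: dict = {}
        x0 = ((X[:, :, None] - self._input_loc)
              / self._input_scale).astype(np.float32)
        x0 *= op.masks[0][None, :, None]
        fb0 = self._flat_basis(self._L32[0], x0, K)
        pre1 = self._conv(fb0, p["theta1"], p["b1"])
        act1 = np.maximum(pre1, 0.0) * op.masks[0][None, :, None]
        pool1, arg1 = _maxpool2(act1)
        fb1 = self._flat_basis(self._L32[1], pool1, K)
        pre2 = self._conv(fb1, p["theta2"], p["b2"])
        act2 = np.maximum(pre2, 0.0) * op.masks[1][None, :, None]
        pool2, arg2 = _maxpool2(act2)
        flat = pool2.reshape(X.shape[0], -1)
        z1 = flat @ p["W1"] + p["c1"]
        a1 = np.maximum(z1, 0.0)
        if train and dropout > 0:
            m1 = ((self.rng.random(a1.shape) >= dropout)
                  / (1 - dropout)).astype(np.float32)
        else:
            m1 = np.ones_like(a1)
        d1 = a1 * m1
        z2 = d1 @ p["W2"] + p["c2"]
        a2 = np.maximum(z2, 0.0)
        if train and dropout > 0:
            m2 = ((self.rng.random(a2.shape) >= dropout)
                  / (1 - dropout)).astype(np.float32)
        else:
            m2 = np.ones_like(a2)
        d2 = a2 * m2
        logits = d2 @ p["W3"] + p["c3"]
        cache.update(x0=x0, fb0=fb0, pre1=pre1, arg1=arg1,
                     pool1=pool1, fb1=fb1, pre2=pre2, arg2=arg2,
                     flat=flat, z1=z1, m1=m1, d1=d1, z2=z2, m2=m2, d2=d2)
        return logits, cache

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def _backward(self, cache: dict, probs: np.ndarray,
                  y: np.ndarray) -> dict:
        p = self.params
        op = self.operator
        K = self.arch.cheb_order
        B = len(y)
        grads = {}
        dlogits = probs.astype(np.float32)
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads["W3"] = cache["d2"].T @ dlogits
        grads["c3"] = dlogits.sum(0)
        dd2 = dlogits @ p["W3"].T
        da2 = dd2 * cache["m2"]
        dz2 = da2 * (cache["z2"] > 0)
        grads["W2"] = cache["d1"].T @ dz2
        grads["c2"] = dz2.sum(0)
        dd1 = dz2 @ p["W2"].T
        da1 = dd1 * cache["m1"]
        dz1 = da1 * (cache["z1"] > 0)
        grads["W1"] = cache["flat"].T @ dz1
        grads["c1"] = dz1.sum(0)
        dflat = dz1 @ p["W1"].T
        n2 = len(op.perms[2])
        dpool2 = dflat.reshape(B, n2, self.arch.filters[1])
        dact2 = _maxpool2_backward(dpool2, cache["arg2"],
                                   len(op.perms[1]))
        dpre2 = dact2 * (cache["pre2"] > 0) * op.masks[1][None, :, None]
        f1, f2 = self.arch.filters
        n1 = len(op.perms[1])
        fb1 = cache["fb1"]
        grads["theta2"] = (
            fb1.reshape(-1, K * f1).T @ dpre2.reshape(-1, f2)
        ).reshape(K, f1, f2)
        grads["b2"] = dpre2.sum((0, 1))
        # back through the Chebyshev expansion of layer 2
        dflat1 = (dpre2.reshape(-1, f2) @ p["theta2"].reshape(K * f1, f2).T
                  ).reshape(B, n1, K, f1).transpose(2, 0, 1, 3)
        dpool1 = _cheb_adjoint_sum(self._L32[1],
                                   np.ascontiguousarray(dflat1))
        dact1 = _maxpool2_backward(dpool1, cache["arg1"],
                                   len(op.perms[0]))
        dpre1 = dact1 * (cache["pre1"] > 0) * op.masks[0][None, :, None]
        grads["theta1"] = (
            cache["fb0"].reshape(-1, K).T @ dpre1.reshape(-1, f1)
        ).reshape(K, 1, f1)
        grads["b1"] = dpre1.sum((0, 1))
        return grads

    def _adam_step(self, grads: dict, lr: float, weight_decay: float):
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = self._adam_t
        alpha = lr * np.sqrt(1 - b2 ** t) / (1 - b1 ** t)
        for key, g in grads.items():
            if weight_decay > 0 and not key.startswith(("b", "c")):
                g = g + weight_decay * self.params[key]
            m, v = self._adam_m[key], self._adam_v[key]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            self.params[key] -= alpha * m / (np.sqrt(v) + eps)

    # public API ---------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray,
            config: TrainConfig) -> "GraphConvNet":
        """Mini-batch training for exactly `config.epochs` passes."""
        if len(np.unique(y)) < 2:
            raise TrainingError("training data contains a single class")
        real = self.operator.masks[0]
        self._input_loc = float(X[:, real].mean())
        self._input_scale = float(max(X[:, real].std(), 1e-6))
        for epoch in range(config.epochs):
            order = self.rng.permutation(len(y))
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, len(y), config.batch_size):
                idx = order[start:start + config.batch_size]
                logits, cache = self._forward(X[idx], True, config.dropout)
                probs = self._softmax(logits)
                eps = 1e-12
                loss = -np.mean(np.log(probs[np.arange(len(idx)),
                                             y[idx]] + eps))
                grads = self._backward(cache, probs, y[idx])
                self._adam_step(grads, config.learning_rate,
                                config.weight_decay)
                epoch_loss += loss
                n_batches += 1
            self.loss_history.append(epoch_loss / max(n_batches, 1))
        final = self.loss_history[-1]
        self.converged = bool(np.isfinite(final)
                              and final <= self.loss_history[0] + 1e-9)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        out = []
        for start in range(0, len(X), 256):
            logits, _ = self._forward(X[start:start + 256], False, 0.0)
            out.append(self._softmax(logits))
        return np.vstack(out)


def prepare_features(dataset: GraphAlignedDataset,
                     operator: GraphOperator) -> np.ndarray:
    """Permute/pad dataset columns into the operator's level-0 ordering."""
    if dataset.genes != operator.vertex_order:
        raise ParameterError(
            "dataset gene order does not match the operator's vertex order")
    return coarsening.perm_features(dataset.X, operator.perms[0])


def train_gcnn(dataset: GraphAlignedDataset, operator: GraphOperator,
               arch: GCNNArchitecture = GCNNArchitecture(),
               config: TrainConfig = TrainConfig()) -> GraphConvNet:
    X = prepare_features(dataset, operator)
    model = GraphConvNet(operator, arch, seed=config.seed)
    return model.fit(X, dataset.y, config)


def compute_metrics(truth: Sequence[int], scores: Sequence[float],
                    cutoff: float = 0.5) -> dict[str, float]:
    """AUC, accuracy and support-weighted F1, all in percent."""
    truth = np.asarray(truth, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(truth) != len(scores):
        raise ParameterError("truth and scores lengths differ")
    if len(np.unique(truth)) < 2:
        raise ParameterError("AUC undefined with a single class")
    pred = (scores >= cutoff).astype(int)
    return {
        "auc": 100.0 * float(roc_auc_score(truth, scores)),
        "accuracy": 100.0 * float(accuracy_score(truth, pred)),
        "f1_weighted": 100.0 * float(f1_score(truth, pred,
                                              average="weighted")),
    }


def cross_validate(dataset: GraphAlignedDataset, operator: GraphOperator,
                   arch: GCNNArchitecture = GCNNArchitecture(),
                   config: TrainConfig = TrainConfig()) -> EvaluationResult:
    """Stratified k-fold cross-validation with per-fold metrics and SEMs."""
    y = dataset.y
    counts = np.bincount(y, minlength=2)
    if counts.min() < config.folds:
        raise ParameterError(
            f"each class needs >= {config.folds} samples for stratification, "
            f"got {counts.tolist()}")
    X = prepare_features(dataset, operator)
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True,
                          random_state=config.seed)
    rows, converged = [], []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        model = GraphConvNet(operator, arch, seed=config.seed * 1000 + fold)
        model.fit(X[tr], y[tr], config)
        scores = model.predict_proba(X[te])[:, 1]
        rows.append(compute_metrics(y[te], scores))
        converged.append(bool(model.converged))
    frame = pd.DataFrame(rows,
                         index=pd.RangeIndex(config.folds, name="fold"))
    return EvaluationResult(frame, converged)
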