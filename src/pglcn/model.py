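"""The pathway graph-learning convolutional network (PGLCN).

Three trainable blocks:

1. Graph learning layer. Node features are projected to a low-dimensional
   embedding g~ = g P; each supported pair (prior adjacency A_ij = 1) gets an
   unnormalized affinity exp(ReLU(a^T |g~_i - g~_j|)), and a row-wise softmax
   over the support of A produces the learned affinity S — row-stochastic by
   construction, with S_ij = 0 wherever A_ij = 0. The layer is trained with
   L1 = sum_ij ||g_i - g_j||^2 S_ij + gamma ||S||_F^2: distant nodes are
   pushed toward small affinity, and the Frobenius term controls sparsity.

2. Simplified graph convolutions X^(k+1) = act(S X^(k) W^(k)). Because S is
   already row-stochastic no Laplacian normalization is applied.

3. A head: per-node linear logits in transductive mode (one fixed graph,
   node labels); in cohort mode each patient owns a pathway graph with
   shared parameters, the conv output is flattened in fixed pathway order
   and passed through fully connected layers to patient-level logits.

The joint objective is L = L1 + lambda * L2 with L2 the cross-entropy over
labeled samples. Unlabeled samples still shape L1 (semi-supervised).

Note the pairwise term uses the elementwise absolute difference
|g~_i - g~_j|; the antisymmetric signed difference (which makes
exp(ReLU(.)) blind to half the pairs) is available via ``signed_diff``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, parameter

_EPS = 1e-12


# ---------------------------------------------------------------- config

@dataclass
class TrainConfig:
    """Training hyperparameters for both modes.

    gamma weights the sparsity term of the graph-learning loss, lam the
    cross-entropy term of the joint loss L = L1 + lam * L2.
    """

    mode: str = "cohort"                    # "cohort" | "transductive"
    embed_dim: int = 4                      # d of the learned embedding, < input dim
    conv_dims: tuple = (64, 64)             # widths of the conv stack
    fc_dims: tuple = (128,)                 # hidden FC widths (cohort mode)
    gamma: float = 0.01
    lam: float = 1.0
    lr: float = 1e-3
    epochs: int = 200
    patience: int = 20
    seed: int = 0
    signed_diff: bool = False
    readout: str = "flatten"                # "flatten" | "mean" (cohort)
    edge_dropout: float = 0.0               # per-epoch drop rate of support edges
    label_smoothing: float = 0.0            # soft targets: keeps logits calibrated

    def __post_init__(self):
        if self.mode not in ("cohort", "transductive"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.gamma < 0 or self.lam < 0 or self.lr <= 0:
            raise ValueError("gamma, lam must be >= 0 and lr > 0")


@dataclass
class GraphLearnerParams:
    """Projection P (input dim x d) and attention vector a (d,)."""

    P: np.ndarray
    a: np.ndarray


# ------------------------------------------------------- functional ops

def support_edges(prior_A: np.ndarray):
    """Directed support of A (both directions of every entry, diag included)."""
    a = np.asarray(prior_A)
    row, col = np.nonzero(a)
    return row.astype(np.intp), col.astype(np.intp)


def graph_learning_layer(features, prior_A, params: GraphLearnerParams, signed_diff=False):
    """Learned affinity S as a dense row-stochastic matrix (numpy in/out).

    S_ij = A_ij exp(ReLU(a^T |g~_i - g~_j|)) / row normalizer, with
    g~ = features @ P. Entries outside the support of A are exactly zero.
    """
    x = np.asarray(features, dtype=float)
    a_mat = np.asarray(prior_A)
    if x.shape[0] != a_mat.shape[0]:
        raise ValueError("feature rows must align with prior_A")
    P = np.asarray(params.P, dtype=float)
    if x.shape[1] != P.shape[0]:
        raise ValueError("feature dim does not match projection P")
    att = np.asarray(params.a, dtype=float).reshape(-1)
    g = x @ P
    row, col = support_edges(a_mat)
    diff = g[row] - g[col]
    if not signed_diff:
        diff = np.abs(diff)
    w = np.exp(np.maximum(diff @ att, 0.0))
    denom = np.zeros(len(x))
    np.add.at(denom, row, w)
    s = np.zeros_like(a_mat, dtype=float)
    s[row, col] = w / denom[row]
    return s


def graph_learning_loss(features, S, gamma: float) -> float:
    """L1 = sum_ij ||g_i - g_j||^2 S_ij + gamma ||S||_F^2 (numpy in/out)."""
    g = np.asarray(features, dtype=float)
    s = np.asarray(S, dtype=float)
    sq = ((g[:, None, :] - g[None, :, :]) ** 2).sum(axis=2)
    return float((sq * s).sum() + gamma * (s**2).sum())


def graph_conv(X, S, W, activation="relu"):
    """One simplified convolution act(S X W) (numpy in/out)."""
    x = np.asarray(X, dtype=float)
    s = np.asarray(S, dtype=float)
    w = np.asarray(W, dtype=float)
    if w.ndim == 0:
        w = w.reshape(1, 1)
    h = s @ x @ w
    if activation in (None, "identity"):
        return h
    if activation == "relu":
        return np.maximum(h, 0.0)
    if callable(activation):
        return activation(h)
    raise ValueError(f"unknown activation {activation!r}")


def cross_entropy_loss(Z, Y, labeled_ids=None) -> float:
    """L2 = -sum_{i in T} sum_j Y_ij ln Z_ij over labeled samples.

    Z rows are class probabilities; Y is one-hot (or an integer label
    vector). Probabilities are clipped to [1e-12, 1 - 1e-12] before the log.
    """
    z = np.asarray(Z, dtype=float)
    y = np.asarray(Y)
    if y.ndim == 1:
        onehot = np.zeros_like(z)
        onehot[np.arange(len(y)), y.astype(int)] = 1.0
        y = onehot
    if labeled_ids is not None:
        idx = np.asarray(labeled_ids, dtype=int)
        z, y = z[idx], y[idx]
    z = np.clip(z, _EPS, 1.0 - _EPS)
    return float(-(y * np.log(z)).sum())


def total_loss(L1: float, L2: float, lam: float) -> float:
    """Joint objective L = L1 + lam * L2."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    return L1 + lam * L2


def softmax(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


# ------------------------------------------------------------ the network

class PGLCN:
    """Graph-learning convolutional network with shared parameters.

    Differentiable forward passes are built on the package's autodiff
    tensors; the public predict methods take and return numpy arrays.
    """

    def __init__(self, in_dim: int, n_classes: int, n_nodes: int, config: TrainConfig):
        if config.embed_dim >= in_dim and in_dim > 1:
            raise ValueError("embed_dim must be smaller than the input feature dim")
        self.config = config
        self.in_dim = in_dim
        self.n_classes = n_classes
        self.n_nodes = n_nodes  # pathways (cohort) or graph nodes (transductive)
        rng = np.random.default_rng(config.seed)
        d = config.embed_dim
        self.P = parameter((in_dim, d), rng)
        self.a = parameter((d, 1), rng)
        self.conv_ws = []
        prev = in_dim
        for width in config.conv_dims:
            self.conv_ws.append(parameter((prev, width), rng))
            prev = width
        if config.mode == "transductive":
            self.head_w = parameter((prev, n_classes), rng)
            self.head_b = parameter(np.zeros(n_classes))
            self.fc = []
        else:
            flat = prev * n_nodes if config.readout == "flatten" else prev
            self.fc = []
            for width in config.fc_dims:
                self.fc.append((parameter((flat, width), rng), parameter(np.zeros(width))))
                flat = width
            self.head_w = parameter((flat, n_classes), rng)
            self.head_b = parameter(np.zeros(n_classes))

    # ------------------------------------------------------------- params
    def parameters(self):
        ps = [self.P, self.a, *self.conv_ws, self.head_w, self.head_b]
        for w, b in self.fc:
            ps.extend([w, b])
        return ps

    def state_dict(self):
        return [p.value.copy() for p in self.parameters()]

    def load_state_dict(self, state):
        for p, v in zip(self.parameters(), state):
            p.value = v.copy()

    def learner_params(self) -> GraphLearnerParams:
        return GraphLearnerParams(P=self.P.value.copy(), a=self.a.value.reshape(-1).copy())

    # ------------------------------------------------------------ affinity
    def _affinity(self, x_t: Tensor, row, col, n: int, edge_vals=None) -> Tensor:
        """Edge-wise learned affinity s over the directed support (E, 1).

        ``edge_vals`` (the explainer's soft mask, in [0, 1] per directed
        edge) multiplies the affinity *after* the row softmax: a masked
        edge's contribution is removed rather than redistributed to its
        row's surviving neighbors, so masking genuinely deletes signal.
        """
        g = x_t @ self.P
        diff = g.take_rows(row) - g.take_rows(col)
        if not self.config.signed_diff:
            diff = diff.abs()
        w = (diff @ self.a).relu().exp()           # (E, 1)
        denom = w.segment_sum(row, n)
        s = w / denom.take_rows(row)
        if edge_vals is not None:
            ev = edge_vals if isinstance(edge_vals, Tensor) else Tensor(edge_vals)
            s = s * ev.reshape(-1, 1)
        return s

    def _conv_stack(self, x_t: Tensor, s: Tensor, row, col, n: int) -> Tensor:
        h = x_t
        for w in self.conv_ws:
            msg = (s * h.take_rows(col)).segment_sum(row, n)
            h = (msg @ w).relu()
        return h

    def _graph_loss(self, x_t: Tensor, s: Tensor, row, col) -> Tensor:
        d2 = ((x_t.take_rows(row) - x_t.take_rows(col)) ** 2).sum(axis=1, keepdims=True)
        return (d2 * s).sum() + self.config.gamma * (s**2).sum()

    # ------------------------------------------------------------ forwards
    def forward_transductive(self, x_t: Tensor, row, col, edge_vals=None):
        """Per-node logits and edge affinities on a single graph."""
        n = x_t.shape[0]
        s = self._affinity(x_t, row, col, n, edge_vals)
        h = self._conv_stack(x_t, s, row, col, n)
        logits = h @ self.head_w + self.head_b.reshape(1, -1)
        return logits, s

    def forward_cohort(self, feats_t: Tensor, row, col, edge_vals=None):
        """Patient-level logits for a batch of per-patient pathway graphs.

        ``feats_t`` is (B, p, f); the batch is evaluated as one
        block-diagonal graph so each patient gets its own affinity from the
        shared learner parameters.
        """
        b, p, f = feats_t.shape
        x = feats_t.reshape(b * p, f)
        e = len(row)
        brow = (np.tile(row, b) + np.repeat(np.arange(b) * p, e)).astype(np.intp)
        bcol = (np.tile(col, b) + np.repeat(np.arange(b) * p, e)).astype(np.intp)
        bvals = None
        if edge_vals is not None:
            ev = edge_vals if isinstance(edge_vals, Tensor) else Tensor(edge_vals)
            tiled = np.tile(np.arange(e), b)
            bvals = ev.reshape(-1, 1).take_rows(tiled).reshape(-1)
        s = self._affinity(x, brow, bcol, b * p, bvals)
        h = self._conv_stack(x, s, brow, bcol, b * p)
        width = h.shape[1]
        if self.config.readout == "flatten":
            z = h.reshape(b, p * width)
        else:
            z = h.reshape(b, p, width).mean(axis=1)
        for w, bias in self.fc:
            z = (z @ w + bias.reshape(1, -1)).relu()
        logits = z @ self.head_w + self.head_b.reshape(1, -1)
        return logits, s, (x, brow, bcol)

    # -------------------------------------------------------- public API
    def predict_logits(self, features, prior_A=None, row=None, col=None):
        """Numpy logits; cohort input (B, p, f) or transductive (n, f)."""
        if row is None or col is None:
            row, col = support_edges(prior_A)
        x = Tensor(np.asarray(features, dtype=float))
        if self.config.mode == "transductive":
            logits, _ = self.forward_transductive(x, row, col)
        else:
            logits, _, _ = self.forward_cohort(x, row, col)
        return logits.value

    def predict_proba(self, features, prior_A=None, row=None, col=None):
        return softmax(self.predict_logits(features, prior_A, row=row, col=col))


def _ce_from_logits(logits: Tensor, labels: np.ndarray, idx: np.ndarray,
                    label_smoothing: float = 0.0) -> Tensor:
    """Summed cross-entropy over ``idx`` from raw logits (stable log-softmax)."""
    z = logits.take_rows(idx)
    shift = z.value.max(axis=1, keepdims=True)  # constant shift, exact gradient
    zs = z - Tensor(shift)
    lse = zs.exp().sum(axis=1, keepdims=True).log()
    logp = zs - lse
    c = z.shape[1]
    onehot = np.full(z.shape, label_smoothing / c)
    onehot[np.arange(len(idx)), np.asarray(labels)[idx].astype(int)] += 1.0 - label_smoothing
    return -(logp * Tensor(onehot)).sum()


@dataclass
class TrainResult:
    model: "PGLCN"
    history: dict = field(default_factory=dict)
    best_epoch: int = -1


def _train_loop(model, loss_fn, val_fn, config: TrainConfig) -> TrainResult:
    opt = Adam(model.parameters(), lr=config.lr)
    history = {"loss": [], "l1": [], "l2": [], "val_loss": []}
    best_val, best_state, best_epoch, wait = np.inf, model.state_dict(), -1, 0
    for epoch in range(config.epochs):
        opt.zero_grad()
        loss, l1, l2 = loss_fn()
        if not np.isfinite(loss.value):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}: {loss.value}")
        loss.backward()
        opt.step()
        val = val_fn()
        history["loss"].append(float(loss.value))
        history["l1"].append(float(l1))
        history["l2"].append(float(l2))
        history["val_loss"].append(float(val))
        if val < best_val - 1e-9:
            best_val, best_state, best_epoch, wait = val, model.state_dict(), epoch, 0
        else:
            wait += 1
            if config.patience and wait >= config.patience:
                break
    model.load_state_dict(best_state)
    return TrainResult(model=model, history=history, best_epoch=best_epoch)


def train_transductive(features, edges, labels, train_idx, val_idx, config: TrainConfig) -> TrainResult:
    """Fit the network on one graph with a labeled train/validation split.

    ``edges`` is an undirected (E, 2) edge list; self-loops are added to the
    support automatically.
    """
    x = np.asarray(features, dtype=float)
    n = x.shape[0]
    labels = np.asarray(labels, dtype=int)
    train_idx = np.asarray(train_idx, dtype=int)
    val_idx = np.asarray(val_idx, dtype=int)
    a = np.eye(n, dtype=int)
    e = np.asarray(edges, dtype=int)
    a[e[:, 0], e[:, 1]] = 1
    a[e[:, 1], e[:, 0]] = 1
    row, col = support_edges(a)
    model = PGLCN(x.shape[1], int(labels.max()) + 1, n, config)
    x_t = Tensor(x)
    drop_rng = np.random.default_rng(config.seed + 1)

    def loss_fn():
        ev = None
        if config.edge_dropout > 0:
            # drop support edges (self-loops kept): forces redundant,
            # distributed reliance on the neighborhood
            keep = (drop_rng.random(len(row)) >= config.edge_dropout) | (row == col)
            ev = keep.astype(float)
        logits, s = model.forward_transductive(x_t, row, col, edge_vals=ev)
        l1 = model._graph_loss(x_t, s, row, col)
        l2 = _ce_from_logits(logits, labels, train_idx, config.label_smoothing)
        return l1 + config.lam * l2, l1.value, l2.value

    def val_fn():
        logits = model.predict_logits(x, row=row, col=col)
        p = softmax(logits)
        return cross_entropy_loss(p, labels, val_idx) / max(len(val_idx), 1)

    result = _train_loop(model, loss_fn, val_fn, config)
    result.history["support"] = (row, col)
    return result


def train_pglcn(features, labels, prior_A, train_idx, val_idx, config: TrainConfig) -> TrainResult:
    """Cohort-mode training: per-patient pathway graphs, patient labels.

    ``features`` is (B, p, 3q); patients outside ``train_idx`` still shape
    the graph-learning loss L1 (semi-supervised) but not the cross-entropy.
    """
    feats = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    train_idx = np.asarray(train_idx, dtype=int)
    val_idx = np.asarray(val_idx, dtype=int)
    row, col = support_edges(np.asarray(prior_A))
    b, p, f = feats.shape
    model = PGLCN(f, int(labels.max()) + 1, p, config)
    x_t = Tensor(feats)

    def loss_fn():
        logits, s, (xflat, brow, bcol) = model.forward_cohort(x_t, row, col)
        l1 = model._graph_loss(xflat, s, brow, bcol) / b
        l2 = _ce_from_logits(logits, labels, train_idx, config.label_smoothing)
        return l1 + config.lam * l2, l1.value, l2.value

    def val_fn():
        p_val = softmax(model.predict_logits(feats[val_idx], row=row, col=col))
        return cross_entropy_loss(p_val, labels[val_idx]) / max(len(val_idx), 1)

    result = _train_loop(model, loss_fn, val_fn, config)
    result.history["support"] = (row, col)
    return result
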