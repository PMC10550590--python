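"""Mask-based explanations of a trained network's predictions.

For a frozen model and one instance (a patient's pathway graph, or a node
of a benchmark graph), an edge mask M and a feature mask F are trained so
that the model, evaluated on the softly masked inputs

    E_s = E (.) sigmoid(M)        X_s = X (.) sigmoid(F)

keeps predicting the original class while the masks stay small and
near-binary. The objective is the sum of

    -log P(yhat | E_s, X_s)                  prediction-preservation
    theta_ee * mean H_b(sigmoid(M))          edge-mask entropy
    theta_fe * mean H_b(sigmoid(F))          feature-mask entropy
    theta_es * mean sigmoid(M)               edge-mask size
    theta_fs * mean sigmoid(F)               feature-mask size

with H_b the binary entropy. This is the standard mutual-information
surrogate: the entropy of the (fixed) model's prediction is mask-independent,
so preserving the predicted class maximizes mutual information between the
prediction and the kept subgraph.

Edge logits are one parameter per unordered supported pair, applied to both
directions (symmetric mask); self-loops are never masked so no softmax row
can lose its support. Explanation quality against ground truth is the ROC
AUC of edge-mask weights over motif-edge indicators, restricted to the
explained node's computation neighborhood.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .autodiff import Adam, Tensor, cat, parameter
from .model import PGLCN, softmax

_EPS = 1e-6


@dataclass
class ExplainerConfig:
    """Mask-training hyperparameters.

    Four independent regularizer weights, one per term; all apply to
    sigmoid-squashed logits. Note the size terms are *means* over mask
    entries, so the size weight plays the role that (coefficient x edge
    count) plays in sum-based implementations — hence edge_size defaults
    well above the sum-convention 0.005. The edge-entropy weight defaults
    to zero: binary-entropy polarization amplifies early optimization noise
    on the small computation subgraphs these masks live on, degrading the
    edge ranking (the entropy terms remain available for sparser, more
    binary masks). Masks start near sigma = 0.88 (init_mean = 2) so the
    first gradients are taken close to the unmasked model's operating
    point. Adam on the mask logits only; the model is frozen.
    """

    lr: float = 0.05
    epochs: int = 100
    edge_ent: float = 0.0
    feat_ent: float = 0.1
    edge_size: float = 0.05
    feat_size: float = 1.0
    init_mean: float = 2.0
    init_sd: float = 0.1
    optimizer: str = "adam"                 # "adam" | "sgd"
    temperature: float = 1.0                # softens logits in the prediction loss
    use_feature_mask: bool = True           # False: features pass through unmasked
    average_from: int | None = None         # Polyak-average sigma(masks) from this epoch on
    seed: int = 0

    def __post_init__(self):
        for name in ("edge_ent", "feat_ent", "edge_size", "feat_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ExplanationMasks:
    """Fitted masks for one explained instance."""

    instance: object                   # patient index or node id
    pairs: np.ndarray                  # (E_u, 2) unordered supported pairs, global ids
    edge_logits: np.ndarray            # (E_u,) symmetrized mask logits
    feature_logits: np.ndarray         # (f,) shared-per-column mask logits
    target: int                        # class the masks preserve
    node_ids: np.ndarray | None = None # computation neighborhood (transductive)
    loss_trace: list = field(default_factory=list)

    @property
    def edge_probs(self) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.edge_logits))

    @property
    def feature_probs(self) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.feature_logits))


@dataclass
class ExplanationResult:
    """Thresholded explanation subgraph plus feature importances."""

    edges: list                        # [(u, v, weight)] kept edges, weight desc
    nodes: list                        # induced node set
    feature_importance: np.ndarray
    auc: float | None = None


# ----------------------------------------------------------------- scoring

def explanation_auc(edge_mask_probs, ground_truth_edge_flags) -> float:
    """ROC AUC of mask scores against motif-edge indicators.

    Equals the fraction of (positive, negative) pairs ranked concordantly,
    ties counted half (Mann-Whitney). Returns NaN when either class is
    absent (undefined; excluded from averages by callers).
    """
    scores = np.asarray(edge_mask_probs, dtype=float)
    flags = np.asarray(ground_truth_edge_flags, dtype=bool)
    if scores.shape != flags.shape:
        raise ValueError("scores and flags must align")
    n_pos = int(flags.sum())
    n_neg = int(len(flags) - n_pos)
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    u = ranks[flags].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ----------------------------------------------------- mask fitting (core)

def _binary_entropy(p: Tensor) -> Tensor:
    pc = p.clip(_EPS, 1.0 - _EPS)
    return -(pc * pc.log()) - ((1.0 - pc) * (1.0 - pc).log())


def _regularizers(edge_logits: Tensor, feat_logits: Tensor, cfg: ExplainerConfig):
    m = edge_logits.sigmoid()
    f = feat_logits.sigmoid()
    return {
        "edge_entropy": cfg.edge_ent * _binary_entropy(m).mean(),
        "feat_entropy": cfg.feat_ent * _binary_entropy(f).mean(),
        "edge_size": cfg.edge_size * m.mean(),
        "feat_size": cfg.feat_size * f.mean(),
    }


def _support_with_pairs(n: int, und_pairs: np.ndarray):
    """Directed support (off-diagonal both ways, then self-loops) and the
    unordered-pair index of each off-diagonal directed edge."""
    row = np.concatenate([und_pairs[:, 0], und_pairs[:, 1], np.arange(n)]).astype(np.intp)
    col = np.concatenate([und_pairs[:, 1], und_pairs[:, 0], np.arange(n)]).astype(np.intp)
    pair_idx = np.concatenate([np.arange(len(und_pairs)), np.arange(len(und_pairs))]).astype(np.intp)
    return row, col, pair_idx


def _directed_edge_vals(edge_logits: Tensor, pair_idx: np.ndarray, n_self: int) -> Tensor:
    off = edge_logits.take_rows(pair_idx).sigmoid()
    return cat([off, Tensor(np.ones(n_self))])


class _Sgd:
    """Plain gradient descent; preserves relative gradient magnitudes across
    mask entries (Adam's per-parameter normalization flattens them)."""

    def __init__(self, params, lr):
        self.params = list(params)
        self.lr = lr

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.value -= self.lr * p.grad


class _Frozen:
    """Temporarily freeze a model's parameters (no gradient bookkeeping)."""

    def __init__(self, model: PGLCN):
        self.model = model

    def __enter__(self):
        self.saved = [p.requires_grad for p in self.model.parameters()]
        for p in self.model.parameters():
            p.requires_grad = False
        return self.model

    def __exit__(self, *exc):
        for p, s in zip(self.model.parameters(), self.saved):
            p.requires_grad = s


def _neg_log_prob(logits: Tensor, row_index: int, target: int, temperature: float = 1.0) -> Tensor:
    z = logits.take_rows(np.asarray([row_index]))
    if temperature != 1.0:
        z = z * (1.0 / temperature)
    shift = z.value.max(axis=1, keepdims=True)
    zs = z - Tensor(shift)
    lse = zs.exp().sum(axis=1, keepdims=True).log()
    onehot = np.zeros(z.shape)
    onehot[0, target] = 1.0
    return -((zs - lse) * Tensor(onehot)).sum()


def _fit_masks(model, forward_fn, n_pairs, n_feats, row_index, target, cfg: ExplainerConfig):
    """Shared optimization loop over edge and feature mask logits."""
    rng = np.random.default_rng(cfg.seed)
    edge_logits = parameter(rng.normal(cfg.init_mean, cfg.init_sd, size=n_pairs))
    if cfg.use_feature_mask:
        feat_logits = parameter(rng.normal(cfg.init_mean, cfg.init_sd, size=n_feats))
    else:  # effectively sigma(F) = 1: features pass through unmasked
        feat_logits = parameter(np.full(n_feats, 12.0))
    mask_params = [edge_logits, feat_logits] if cfg.use_feature_mask else [edge_logits]
    if cfg.optimizer == "sgd":
        opt = _Sgd(mask_params, lr=cfg.lr)
    else:
        opt = Adam(mask_params, lr=cfg.lr)
    trace = []
    avg_edge = np.zeros(n_pairs)
    avg_feat = np.zeros(n_feats)
    n_avg = 0
    with _Frozen(model):
        for epoch in range(cfg.epochs):
            opt.zero_grad()
            logits = forward_fn(edge_logits, feat_logits)
            loss = _neg_log_prob(logits, row_index, target, cfg.temperature)
            for term in _regularizers(edge_logits, feat_logits, cfg).values():
                loss = loss + term
            if not np.isfinite(loss.value):
                raise FloatingPointError("non-finite explainer loss")
            trace.append(float(loss.value))
            loss.backward()
            opt.step()
            if cfg.average_from is not None and epoch >= cfg.average_from:
                avg_edge += _sigmoid_np(edge_logits.value)
                avg_feat += _sigmoid_np(feat_logits.value)
                n_avg += 1
    if n_avg:
        # trajectory-averaged masks: robust to the stopping epoch, combines
        # the graded early regime with the sparse late regime
        return _logit_np(avg_edge / n_avg), _logit_np(avg_feat / n_avg), trace
    return edge_logits.value.copy(), feat_logits.value.copy(), trace


def _sigmoid_np(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit_np(p):
    pc = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(pc / (1 - pc))


# ---------------------------------------------------- transductive explain

def khop_subgraph(edges: np.ndarray, node: int, k: int):
    """Nodes within k hops of ``node`` and the induced undirected pairs."""
    adj = {}
    for u, v in np.asarray(edges, dtype=int):
        adj.setdefault(int(u), set()).add(int(v))
        adj.setdefault(int(v), set()).add(int(u))
    seen = {int(node): 0}
    queue = deque([(int(node), 0)])
    while queue:
        u, d = queue.popleft()
        if d == k:
            continue
        for v in adj.get(u, ()):  # noqa: B905
            if v not in seen:
                seen[v] = d + 1
                queue.append((v, d + 1))
    nodes = np.asarray(sorted(seen), dtype=int)
    keep = set(nodes.tolist())
    pairs = [
        (u, v)
        for u, v in ((min(a, b), max(a, b)) for a, b in np.asarray(edges, dtype=int))
        if u in keep and v in keep
    ]
    pairs = sorted(set(pairs))
    return nodes, np.asarray(pairs, dtype=int).reshape(-1, 2)


def fit_node_explanation(
    model: PGLCN,
    features: np.ndarray,
    edges: np.ndarray,
    node: int,
    config: ExplainerConfig | None = None,
) -> ExplanationMasks:
    """Explain one node's prediction on a single (transductive) graph.

    The mask is trained on the node's computation neighborhood: the k-hop
    subgraph with k = number of convolution layers. The preserved target is
    the model's own full-graph prediction for the node.
    """
    cfg = config or ExplainerConfig()
    x = np.asarray(features, dtype=float)
    k = len(model.conv_ws)
    nodes, pairs = khop_subgraph(edges, node, k)
    if len(pairs) == 0:
        raise ValueError(f"node {node} has no edges within {k} hops")
    local = {g: i for i, g in enumerate(nodes)}
    lpairs = np.asarray([(local[u], local[v]) for u, v in pairs], dtype=int)
    n_sub = len(nodes)
    row, col, pair_idx = _support_with_pairs(n_sub, lpairs)
    x_sub = x[nodes]
    v_local = local[int(node)]

    full_proba = model.predict_proba(x, row=None, col=None, prior_A=_dense_from_edges(len(x), edges))
    target = int(np.argmax(full_proba[int(node)]))

    def forward(edge_logits, feat_logits):
        ev = _directed_edge_vals(edge_logits, pair_idx, n_sub)
        xm = Tensor(x_sub) * feat_logits.sigmoid().reshape(1, -1)
        logits, _ = model.forward_transductive(xm, row, col, edge_vals=ev)
        return logits

    m, f, trace = _fit_masks(model, forward, len(lpairs), x.shape[1], v_local, target, cfg)
    return ExplanationMasks(
        instance=int(node),
        pairs=pairs,
        edge_logits=m,
        feature_logits=f,
        target=target,
        node_ids=nodes,
        loss_trace=trace,
    )


def _dense_from_edges(n: int, edges: np.ndarray) -> np.ndarray:
    a = np.eye(n, dtype=int)
    e = np.asarray(edges, dtype=int)
    a[e[:, 0], e[:, 1]] = 1
    a[e[:, 1], e[:, 0]] = 1
    return a


def explain_benchmark_nodes(model, bench, nodes, config=None):
    """Per-node explanation AUCs on a benchmark graph.

    For each node: fit masks on its computation neighborhood, score the
    neighborhood's off-diagonal edges against the motif-edge ground truth.
    Returns (aucs, masks); nodes whose neighborhood lacks a positive or a
    negative edge yield NaN and are excluded from averages downstream.
    """
    motif_pairs = {
        (min(u, v), max(u, v))
        for (u, v), flag in zip(bench.edges, bench.motif_edge_flags)
        if flag
    }
    aucs, fitted = [], []
    for node in nodes:
        masks = fit_node_explanation(model, bench.node_features, bench.edges, int(node), config)
        flags = np.asarray([(u, v) in motif_pairs for u, v in masks.pairs], dtype=bool)
        aucs.append(explanation_auc(masks.edge_probs, flags))
        fitted.append(masks)
    return np.asarray(aucs), fitted


# --------------------------------------------------------- cohort explain

def fit_explanation(
    model: PGLCN,
    instance_features: np.ndarray,
    prior_A: np.ndarray,
    config: ExplainerConfig | None = None,
    instance: object = None,
) -> ExplanationMasks:
    """Explain one patient's prediction in cohort mode.

    The edge mask covers the off-diagonal support of the pathway prior; the
    feature mask is shared across pathway rows (one logit per K_p column).
    """
    cfg = config or ExplainerConfig()
    x = np.asarray(instance_features, dtype=float)
    a = np.asarray(prior_A)
    p = a.shape[0]
    iu, ju = np.nonzero(np.triu(a, k=1))
    pairs = np.column_stack([iu, ju])
    row, col, pair_idx = _support_with_pairs(p, pairs)
    target = int(np.argmax(model.predict_proba(x[None, :, :], row=row, col=col)[0]))

    def forward(edge_logits, feat_logits):
        ev = _directed_edge_vals(edge_logits, pair_idx, p)
        xm = Tensor(x[None, :, :]) * feat_logits.sigmoid().reshape(1, 1, -1)
        logits, _, _ = model.forward_cohort(xm, row, col, edge_vals=ev)
        return logits

    m, f, trace = _fit_masks(model, forward, len(pairs), x.shape[1], 0, target, cfg)
    return ExplanationMasks(
        instance=instance,
        pairs=pairs,
        edge_logits=m,
        feature_logits=f,
        target=target,
        loss_trace=trace,
    )


# ------------------------------------------------------------ evaluation

def masked_forward(model: PGLCN, features, prior_A, masks: ExplanationMasks):
    """Class probabilities of the frozen model under the fitted masks.

    Evaluates the model on E (.) sigmoid(M) and X (.) sigmoid(F); self-loops
    stay unmasked. Cohort mode expects a single instance's (p, f) features.
    """
    x = np.asarray(features, dtype=float)
    sig_f = masks.feature_probs
    if model.config.mode == "transductive":
        nodes = masks.node_ids
        local = {g: i for i, g in enumerate(nodes)}
        lpairs = np.asarray([(local[u], local[v]) for u, v in masks.pairs], dtype=int)
        row, col, pair_idx = _support_with_pairs(len(nodes), lpairs)
        ev = np.concatenate([masks.edge_probs[pair_idx], np.ones(len(nodes))])
        xm = Tensor(x[nodes] * sig_f[None, :])
        logits, _ = model.forward_transductive(xm, row, col, edge_vals=Tensor(ev))
        return softmax(logits.value)
    p = np.asarray(prior_A).shape[0]
    row, col, pair_idx = _support_with_pairs(p, masks.pairs)
    ev = np.concatenate([masks.edge_probs[pair_idx], np.ones(p)])
    xm = Tensor((x * sig_f[None, :])[None, :, :])
    logits, _, _ = model.forward_cohort(xm, row, col, edge_vals=Tensor(ev))
    return softmax(logits.value)[0]


def explainer_loss(model, features, prior_A, masks: ExplanationMasks, config=None):
    """Loss components for fitted masks (diagnostic; numpy in/out)."""
    cfg = config or ExplainerConfig()
    proba = np.atleast_2d(masked_forward(model, features, prior_A, masks))
    if model.config.mode == "transductive":
        row_idx = int(np.where(masks.node_ids == masks.instance)[0][0])
    else:
        row_idx = 0
    pred_term = float(-np.log(max(proba[row_idx, masks.target], 1e-12)))
    comps = {
        "pred": pred_term,
        "edge_entropy": cfg.edge_ent * float(_np_binary_entropy(masks.edge_probs).mean()),
        "feat_entropy": cfg.feat_ent * float(_np_binary_entropy(masks.feature_probs).mean()),
        "edge_size": cfg.edge_size * float(masks.edge_probs.mean()),
        "feat_size": cfg.feat_size * float(masks.feature_probs.mean()),
    }
    comps["total"] = float(sum(comps.values()))
    return comps


def _np_binary_entropy(p: np.ndarray) -> np.ndarray:
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    return -pc * np.log(pc) - (1.0 - pc) * np.log(1.0 - pc)


def extract_subgraph(masks: ExplanationMasks, top_k: int | None = None, threshold: float | None = None) -> ExplanationResult:
    """Keep the top-k edges by mask weight (or all with weight >= threshold)."""
    probs = masks.edge_probs
    order = np.argsort(-probs, kind="stable")
    if top_k is not None:
        keep = order[: min(top_k, len(order))]
    elif threshold is not None:
        keep = order[probs[order] >= threshold]
    else:
        keep = order
    edges = [(int(masks.pairs[i, 0]), int(masks.pairs[i, 1]), float(probs[i])) for i in keep]
    nodes = sorted({n for u, v, _ in edges for n in (u, v)})
    return ExplanationResult(
        edges=edges,
        nodes=nodes,
        feature_importance=masks.feature_probs.copy(),
    )
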