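"""Model evaluation: SMOTE balancing, repeated stratified CV, metrics,
and the baseline-comparison harness.

The protocol is 5-fold stratified cross-validation repeated 5 times: each
fold's 20% is the test set, the remaining 80% is stratified-split again
into training (80%) and validation (20%). Minority oversampling (SMOTE) is
applied inside the training partition only, after splitting, so synthetic
samples can never leak into validation or test sets. (The leakage-prone
"balance the whole cohort first" ordering is available behind a flag on
the comparison harness for protocol parity experiments.)
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .model import TrainConfig, softmax, train_pglcn


# ------------------------------------------------------------------ SMOTE

def smote_oversample(features, labels, k_neighbors: int = 5, seed: int = 0):
    """Synthetic minority oversampling until the two classes are equal.

    Each synthetic sample is x + u * (x_nn - x) with u ~ Uniform(0, 1) and
    x_nn one of the k nearest minority neighbors of a random minority point
    x; originals are retained. Returns (features, labels, synthetic_flag):
    the flag marks generated rows, so leakage checks can trace them.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote_oversample expects binary labels")
    flags = np.zeros(len(y), dtype=bool)
    if counts[0] == counts[1]:
        return x, y, flags
    minority = classes[np.argmin(counts)]
    x_min = x[y == minority]
    n_needed = int(abs(counts[0] - counts[1]))
    if len(x_min) < 2:
        raise ValueError("SMOTE needs at least 2 minority samples")
    k = k_neighbors
    if len(x_min) <= k:
        k = len(x_min) - 1
        warnings.warn(
            f"k_neighbors reduced to {k}: only {len(x_min)} minority samples",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x_min)
    _, idx = nn.kneighbors(x_min)  # column 0 is the point itself
    base = rng.integers(0, len(x_min), n_needed)
    pick = rng.integers(1, k + 1, n_needed)
    u = rng.random(n_needed)
    x_syn = x_min[base] + u[:, None] * (x_min[idx[base, pick]] - x_min[base])
    x_out = np.vstack([x, x_syn])
    y_out = np.concatenate([y, np.full(n_needed, minority)])
    flags = np.concatenate([flags, np.ones(n_needed, dtype=bool)])
    return x_out, y_out, flags


# ---------------------------------------------------------------- CV plan

@dataclass
class CvPlan:
    """Index bookkeeping for 5-repeat stratified 5-fold cross-validation."""

    splits: list          # list of dicts {repeat, fold, train, val, test}
    folds: int = 5
    repeats: int = 5
    seed: int = 0


def make_cv_plan(labels, seed: int = 0, folds: int = 5, repeats: int = 5,
                 val_fraction: float = 0.2) -> CvPlan:
    """Stratified 5x5 CV: per repeat, 5 folds; each fold's complement is
    stratified-split 80/20 into train/validation."""
    y = np.asarray(labels, dtype=int)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(f"every class needs at least {folds} samples")
    splits = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + 1000 * rep)
        for fold, (rest, test) in enumerate(skf.split(np.zeros(len(y)), y)):
            train, val = train_test_split(
                rest,
                test_size=val_fraction,
                stratify=y[rest],
                random_state=seed + 1000 * rep + fold,
            )
            splits.append({
                "repeat": rep,
                "fold": fold,
                "train": np.sort(train),
                "val": np.sort(val),
                "test": np.sort(test),
            })
    return CvPlan(splits=splits, folds=folds, repeats=repeats, seed=seed)


# ----------------------------------------------------------------- metrics

def compute_metrics(true_labels, scores, threshold: float = 0.5) -> dict:
    """Accuracy, recall, precision, F1 (positive class) and ranking AUC.

    ``scores`` are positive-class probabilities; thresholded at 0.5 for the
    confusion-matrix metrics. AUC is None when only one class is present.
    """
    y = np.asarray(true_labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    acc = (tp + tn) / max(len(y), 1)
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    auc = None
    if len(np.unique(y)) == 2:
        auc = float(roc_auc_score(y, s))
    return {"accuracy": acc, "recall": recall, "f1": f1, "auc": auc, "precision": precision}


# ------------------------------------------------------- comparison harness

_METRICS = ("accuracy", "recall", "f1", "auc", "precision", "time")


@dataclass
class MetricReport:
    """Mean +- sample sd of each metric over the CV runs."""

    model: str
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)
    runs: list = field(default_factory=list)

    def row(self) -> dict:
        out = {"model": self.model}
        for m in _METRICS:
            out[m] = f"{self.mean[m]:.3f} ± {self.sd[m]:.3f}" if self.mean[m] is not None else "—"
        return out


def _baseline(name: str, seed: int):
    if name == "logreg":
        # L2 penalty (the sklearn default)
        return LogisticRegression(max_iter=2000, random_state=seed)
    if name == "svm-rbf":
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if name == "svm-linear":
        return SVC(kernel="linear", probability=True, random_state=seed)
    if name == "rf":
        return RandomForestClassifier(random_state=seed)
    if name == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    if name == "dtree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "dummy":
        return DummyClassifier(strategy="prior")
    raise ValueError(f"unknown model name {name!r}")

BASELINE_NAMES = ("logreg", "svm-rbf", "svm-linear", "rf", "adaboost", "dtree")


def run_model_comparison(
    features,
    labels,
    model_specs,
    cv_plan: CvPlan,
    prior_A=None,
    pglcn_config: TrainConfig | None = None,
    smote: bool = True,
    smote_before_split: bool = False,
    k_neighbors: int = 5,
) -> dict:
    """Train/evaluate each named model on identical CV splits.

    ``features`` is the pathway feature tensor (B, p, f); sklearn baselines
    see the flattened (B, p*f) matrix, the network sees the tensor with the
    pathway prior ``prior_A``. SMOTE (when enabled) is fit inside each
    training partition only, unless ``smote_before_split`` deliberately
    reproduces the leakage-prone cohort-level ordering.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if smote_before_split:
        # literal ordering: balance the whole cohort, then split. Synthetic
        # samples can land in validation/test sets — leakage-prone; kept only
        # for protocol parity experiments.
        shape = x.shape[1:]
        flat0, y, _ = smote_oversample(x.reshape(len(x), -1), y, k_neighbors, cv_plan.seed)
        x = flat0.reshape(len(flat0), *shape)
        cv_plan = make_cv_plan(y, seed=cv_plan.seed, folds=cv_plan.folds, repeats=cv_plan.repeats)
        smote = False
    flat = x.reshape(len(x), -1)
    reports = {}
    for spec in model_specs:
        runs = []
        for split in cv_plan.splits:
            tr, va, te = split["train"], split["val"], split["test"]
            seed = cv_plan.seed + 7919 * split["repeat"] + split["fold"]
            t0 = time.perf_counter()
            if spec == "pglcn":
                xt, yt = x[tr], y[tr]
                if smote:
                    ft, yt, _ = smote_oversample(flat[tr], y[tr], k_neighbors, seed)
                    xt = ft.reshape(len(ft), x.shape[1], x.shape[2])
                cfg = pglcn_config or TrainConfig(mode="cohort")
                cfg = TrainConfig(**{**cfg.__dict__, "seed": seed})
                xfit = np.concatenate([xt, x[va]])
                yfit = np.concatenate([yt, y[va]])
                res = train_pglcn(
                    xfit, yfit, prior_A,
                    train_idx=np.arange(len(xt)),
                    val_idx=np.arange(len(xt), len(xfit)),
                    config=cfg,
                )
                scores = softmax(res.model.predict_logits(x[te], prior_A=prior_A))[:, 1]
            else:
                xt, yt = flat[tr], y[tr]
                if smote:
                    xt, yt, _ = smote_oversample(xt, yt, k_neighbors, seed)
                clf = _baseline(spec, seed)
                clf.fit(xt, yt)
                scores = clf.predict_proba(flat[te])[:, 1]
            elapsed = time.perf_counter() - t0
            m = compute_metrics(y[te], scores)
            m["time"] = elapsed
            runs.append(m)
        rep = MetricReport(model=spec, runs=runs)
        for metric in _METRICS:
            vals = [r[metric] for r in runs if r[metric] is not None]
            rep.mean[metric] = float(np.mean(vals)) if vals else None
            rep.sd[metric] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        reports[spec] = rep
    return reports
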