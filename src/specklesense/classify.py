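"""Kernel Naïve Bayes classification of glucose levels.

The classifier applies Bayes' rule under conditional independence of the
features given the class,

    P(y = k | x_1..x_p)  ∝  pi(y = k) * prod_j f_kj(x_j),

with each class-conditional feature density f_kj estimated
nonparametrically by a triangle-kernel KDE,

    f_kj(x) = (1 / (n_k h_j)) sum_v K((x - v) / h_j),
    K(u) = 1 - |u|  for |u| <= 1,  else 0,

centered on the class's training values.  The per-feature bandwidth is a
single dimensionless ``h`` scaled by that feature's training standard
deviation.  Posteriors are computed in log space; when a test point falls
outside every class's kernel support the posterior falls back to the
priors (a documented degenerate rule, not an error).

Evaluation follows the study protocol: a stratified 60/40 holdout and a
stratified 5-fold cross-validation with the bandwidth chosen from a grid
by mean CV accuracy.  Windows cut from one recording stay within a single
fold (grouped stratification) so overlapping segments cannot leak between
training and validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .exceptions import ValidationError
from . import lockin

__all__ = [
    "FeatureMatrix",
    "NBModel",
    "EvalReport",
    "segment_features",
    "concat_features",
    "fit_nb",
    "predict",
    "predict_batch",
    "holdout_eval",
    "cross_validate",
    "compute_metrics",
    "default_h_grid",
]


# --------------------------------------------------------------------------
# feature construction
# --------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Windowed observations with labels and recording provenance."""

    X: np.ndarray                 # (n, p)
    y: np.ndarray                 # (n,) class labels (glucose mg/dl)
    groups: np.ndarray            # (n,) recording ids
    offsets: np.ndarray           # (n,) window start sample

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("X must be 2-D (observations x features)")
        if not np.all(np.isfinite(X)):
            raise ValidationError("feature matrix contains non-finite entries")
        n = X.shape[0]
        for name in ("y", "groups", "offsets"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} length must match X rows")
        self.X = X
        self.y = np.asarray(self.y)
        self.groups = np.asarray(self.groups)
        self.offsets = np.asarray(self.offsets)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X,
                          columns=[f"x{j}" for j in range(self.n_features)])
        df.insert(0, "recording_id", self.groups)
        df.insert(1, "offset", self.offsets)
        df["label"] = self.y
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        feat_cols = [c for c in df.columns
                     if c not in ("recording_id", "offset", "label")]
        return cls(X=df[feat_cols].to_numpy(float),
                   y=df["label"].to_numpy(),
                   groups=df["recording_id"].to_numpy(),
                   offsets=df["offset"].to_numpy())


def segment_features(
    trace,
    window: int,
    hop: int,
    label,
    recording_id: str = "",
    normalize_rows: bool = False,
    transform: str = "none",
) -> FeatureMatrix:
    """Cut a filtered trace into overlapping fixed-length windows.

    Rows are the windows [i*hop, i*hop + window); the row count is
    floor((len - window) / hop) + 1.  With ``normalize_rows`` each window
    is rescaled to unit maximum absolute value; the default keeps the raw
    band-filtered amplitudes, because the drive-tone amplitude is the
    quantity that separates glucose levels and per-window rescaling would
    discard it.

    ``transform="sorted-abs"`` replaces each window by the descending
    order statistics of its absolute values.  For a narrowband tone the
    window's phase is a nuisance variable; sorting the rectified samples
    removes it while preserving the amplitude scale exactly, so each
    feature concentrates around amplitude x (a fixed quantile of |sin|)
    instead of sweeping the tone's full swing.
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1:
        raise ValidationError("trace must be 1-D")
    if window > x.size:
        raise ValidationError(
            f"window ({window}) exceeds trace length ({x.size})")
    if hop < 1:
        raise ValidationError("hop must be >= 1")
    if transform not in ("none", "sorted-abs"):
        raise ValidationError(f"unknown transform {transform!r}")
    n_rows = (x.size - window) // hop + 1
    offsets = np.arange(n_rows) * hop
    rows = np.stack([x[o:o + window] for o in offsets])
    if normalize_rows:
        rows = np.stack([lockin.normalize(r) for r in rows])
    if transform == "sorted-abs":
        rows = np.sort(np.abs(rows), axis=1)[:, ::-1]
    return FeatureMatrix(
        X=rows,
        y=np.full(n_rows, label),
        groups=np.full(n_rows, recording_id, dtype=object),
        offsets=offsets,
    )


def concat_features(parts: list[FeatureMatrix]) -> FeatureMatrix:
    if not parts:
        raise ValidationError("no feature matrices to concatenate")
    return FeatureMatrix(
        X=np.vstack([p.X for p in parts]),
        y=np.concatenate([p.y for p in parts]),
        groups=np.concatenate([p.groups for p in parts]),
        offsets=np.concatenate([p.offsets for p in parts]),
    )


# --------------------------------------------------------------------------
# triangle-kernel Naive Bayes
# --------------------------------------------------------------------------

@dataclass
class NBModel:
    """Fitted priors plus per-class per-feature triangle-kernel KDEs."""

    classes: np.ndarray                      # sorted ascending
    priors: np.ndarray                       # (K,), sums to 1
    train_values: dict                       # class -> (n_k, p) array
    bandwidth: float                         # dimensionless h
    feature_scale: np.ndarray                # (p,) training std per feature

    @property
    def n_features(self) -> int:
        return self.feature_scale.size

    @property
    def bandwidths(self) -> np.ndarray:
        """Effective per-feature bandwidth h_j = h * scale_j."""
        return self.bandwidth * self.feature_scale

    def to_json(self) -> str:
        return json.dumps({
            "classes": self.classes.tolist(),
            "priors": self.priors.tolist(),
            "bandwidth": self.bandwidth,
            "feature_scale": self.feature_scale.tolist(),
            "train_values": {str(k): v.tolist()
                             for k, v in self.train_values.items()},
        }, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "NBModel":
        d = json.loads(text)
        classes = np.asarray(d["classes"])
        return cls(
            classes=classes,
            priors=np.asarray(d["priors"]),
            bandwidth=float(d["bandwidth"]),
            feature_scale=np.asarray(d["feature_scale"]),
            train_values={k: np.asarray(d["train_values"][str(k)])
                          for k in classes},
        )


def fit_nb(features: FeatureMatrix, bandwidth: float) -> NBModel:
    """Fit priors and kernel densities from a training feature matrix.

    Priors are empirical class frequencies.  The per-feature kernel
    density of class k is the mean of triangle kernels of width
    h_j = bandwidth * std_j centered on the class's training values,
    where std_j is the global training standard deviation of feature j
    (unit scale is substituted for constant features).
    """
    if bandwidth <= 0:
        raise ValidationError("bandwidth must be > 0")
    classes = np.unique(features.y)
    if classes.size < 1:
        raise ValidationError("no training observations")
    counts = np.array([(features.y == k).sum() for k in classes])
    if np.any(counts == 0):
        raise ValidationError("every class needs >= 1 training observation")
    scale = features.X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    train = {k: features.X[features.y == k] for k in classes}
    return NBModel(classes=classes,
                   priors=counts / counts.sum(),
                   train_values={k: np.ascontiguousarray(v)
                                 for k, v in train.items()},
                   bandwidth=float(bandwidth),
                   feature_scale=scale)


def _class_log_likelihood(model: NBModel, X: np.ndarray) -> np.ndarray:
    """Summed log kernel densities, shape (n, K); -inf where density is 0."""
    n = X.shape[0]
    h = model.bandwidths                      # (p,)
    out = np.empty((n, model.classes.size))
    for ki, k in enumerate(model.classes):
        v = model.train_values[k]             # (n_k, p)
        u = np.abs(X[:, None, :] - v[None, :, :]) / h[None, None, :]
        kern = np.clip(1.0 - u, 0.0, None)
        dens = kern.mean(axis=1) / h[None, :]  # (n, p)
        with np.errstate(divide="ignore"):
            out[:, ki] = np.where(dens > 0, np.log(dens,
                                                   where=dens > 0,
                                                   out=np.zeros_like(dens)),
                                  -np.inf).sum(axis=1)
    return out


def predict_batch(model: NBModel,
                  X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior matrix (n, K) and predicted class per row.

    Log-space evaluation of the Naive Bayes posterior; rows whose
    likelihood vanishes for every class fall back to the priors.  Ties
    resolve to the lowest glucose class (classes are sorted ascending).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValidationError(
            f"X must be (n, {model.n_features}); got {X.shape}")
    loglik = _class_log_likelihood(model, X)
    with np.errstate(divide="ignore"):
        logpost = loglik + np.log(model.priors)[None, :]
    dead = ~np.isfinite(logpost).any(axis=1)
    peak = np.max(logpost, axis=1, keepdims=True)
    peak[dead.nonzero()[0]] = 0.0
    w = np.exp(logpost - peak)
    w[dead] = model.priors[None, :]
    posterior = w / w.sum(axis=1, keepdims=True)
    predicted = model.classes[np.argmax(posterior, axis=1)]
    return posterior, predicted


def predict(model: NBModel, x) -> tuple[np.ndarray, object]:
    """Posterior over classes and the MAP class for one feature vector."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError("x must be a 1-D feature vector")
    posterior, predicted = predict_batch(model, x[None, :])
    return posterior[0], predicted[0]


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Confusion matrix and the metrics derived from it."""

    classes: np.ndarray
    confusion: np.ndarray                     # (K, K) true x predicted
    overall_accuracy: float                   # fraction in [0, 1]
    per_class: dict                           # metric name -> (K,) array
    seed: int | None = None
    fold_assignments: np.ndarray | None = None
    selected_bandwidth: float | None = None

    def to_json(self) -> str:
        return json.dumps({
            "classes": self.classes.tolist(),
            "confusion": self.confusion.tolist(),
            "overall_accuracy": self.overall_accuracy,
            "per_class": {k: v.tolist() for k, v in self.per_class.items()},
            "seed": self.seed,
            "fold_assignments": None if self.fold_assignments is None
            else self.fold_assignments.tolist(),
            "selected_bandwidth": self.selected_bandwidth,
        }, sort_keys=True)

    def confusion_frame(self) -> pd.DataFrame:
        """Confusion matrix as a labeled DataFrame (rows = true class)."""
        labels = [str(c) for c in self.classes]
        return pd.DataFrame(self.confusion, index=labels, columns=labels)

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        d = json.loads(text)
        return cls(
            classes=np.asarray(d["classes"]),
            confusion=np.asarray(d["confusion"], dtype=int),
            overall_accuracy=float(d["overall_accuracy"]),
            per_class={k: np.asarray(v) for k, v in d["per_class"].items()},
            seed=d.get("seed"),
            fold_assignments=None if d.get("fold_assignments") is None
            else np.asarray(d["fold_assignments"]),
            selected_bandwidth=d.get("selected_bandwidth"),
        )


def compute_metrics(confusion) -> dict:
    """Confusion-matrix-derived metrics.

    Returns per-class ``accuracy_pct`` ((TP+TN)/total in percent),
    ``precision``, ``recall`` and ``f1`` as fractions, plus
    ``overall_accuracy`` (trace/total, fraction).  F1 is 2PR/(P+R), 0
    when P + R = 0.
    """
    C = np.asarray(confusion)
    if C.ndim != 2 or C.shape[0] != C.shape[1] or C.size == 0:
        raise ValidationError("confusion matrix must be square and nonempty")
    if np.any(C < 0) or not np.allclose(C, np.round(C)):
        raise ValidationError("confusion matrix must hold nonnegative counts")
    C = C.astype(np.int64)
    total = C.sum()
    if total == 0:
        raise ValidationError("confusion matrix is empty (no observations)")
    tp = np.diag(C).astype(float)
    row = C.sum(axis=1).astype(float)          # support per true class
    col = C.sum(axis=0).astype(float)          # predictions per class
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(row > 0, tp / row, 0.0)
        precision = np.where(col > 0, tp / col, 0.0)
    pr = precision + recall
    f1 = np.where(pr > 0, 2.0 * precision * recall / np.where(pr > 0, pr, 1.0),
                  0.0)
    tn = total - row - col + tp
    accuracy_pct = 100.0 * (tp + tn) / total
    return {
        "accuracy_pct": accuracy_pct,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "overall_accuracy": float(tp.sum() / total),
    }


def _confusion(classes: np.ndarray, y_true: np.ndarray,
               y_pred: np.ndarray) -> np.ndarray:
    idx = {k: i for i, k in enumerate(classes)}
    C = np.zeros((classes.size, classes.size), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        C[idx[t], idx[p]] += 1
    return C


def _report(classes, y_true, y_pred, seed=None, folds=None,
            selected_h=None) -> EvalReport:
    C = _confusion(classes, y_true, y_pred)
    metrics = compute_metrics(C)
    overall = metrics.pop("overall_accuracy")
    return EvalReport(classes=classes, confusion=C,
                      overall_accuracy=overall, per_class=metrics,
                      seed=seed, fold_assignments=folds,
                      selected_bandwidth=selected_h)


def holdout_eval(
    features: FeatureMatrix,
    train_fraction: float = 0.6,
    bandwidth: float = 0.5,
    seed: int | None = None,
) -> EvalReport:
    """Stratified random train/test split (60/40 by default).

    Observations of every class are shuffled and split independently so
    class balance carries over; the model is fit on the training part and
    scored on the rest.  Deterministic for a fixed seed.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValidationError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    classes = np.unique(features.y)
    train_idx, test_idx = [], []
    for k in classes:
        rows = np.flatnonzero(features.y == k)
        if rows.size < 2:
            raise ValidationError(
                f"class {k} has fewer than 2 observations")
        rows = rng.permutation(rows)
        n_train = int(round(train_fraction * rows.size))
        n_train = min(max(n_train, 1), rows.size - 1)
        train_idx.extend(rows[:n_train])
        test_idx.extend(rows[n_train:])
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    model = fit_nb(FeatureMatrix(features.X[train_idx], features.y[train_idx],
                                 features.groups[train_idx],
                                 features.offsets[train_idx]), bandwidth)
    _, y_pred = predict_batch(model, features.X[test_idx])
    return _report(classes, features.y[test_idx], y_pred, seed=seed)


def default_h_grid() -> np.ndarray:
    """Log-spaced bandwidth grid used by the deterministic grid search."""
    return np.logspace(np.log10(0.05), np.log10(2.0), 10)


def _vote_by_group(y_true, y_pred, groups, classes):
    """Majority vote of window predictions within each recording.

    Returns per-group (true, predicted) label arrays; ties resolve to
    the lowest glucose class.
    """
    g_true, g_pred = [], []
    order = {k: i for i, k in enumerate(classes)}
    for g in pd.unique(groups):
        rows = groups == g
        g_true.append(y_true[rows][0])
        votes = pd.Series(y_pred[rows]).value_counts()
        top = votes.max()
        winners = sorted(votes[votes == top].index, key=lambda c: order[c])
        g_pred.append(winners[0])
    return np.asarray(g_true), np.asarray(g_pred)


def cross_validate(
    features: FeatureMatrix,
    k: int = 5,
    h_grid=None,
    seed: int | None = None,
    aggregate: str = "window",
) -> tuple[EvalReport, float]:
    """Stratified k-fold CV with grid-search bandwidth selection.

    Folds are near-equal in size and stratified by class; when the
    feature matrix carries more groups (recordings) than folds, whole
    recordings are assigned to folds (grouped stratification) so windows
    of one recording never straddle the train/validation boundary.  Every
    observation is validated exactly once.  The bandwidth with the best
    mean out-of-fold accuracy wins (ties -> smaller h); the returned
    report aggregates the out-of-fold predictions at that bandwidth.

    ``aggregate="recording"`` treats the recording as the observation
    unit: out-of-fold window predictions are majority-voted within each
    recording, and both bandwidth selection and the report work on
    recording-level labels.  Windows of one recording are repeated looks
    at the same physical measurement, so this is the natural unit for
    accuracy.
    """
    if aggregate not in ("window", "recording"):
        raise ValidationError(f"unknown aggregate {aggregate!r}")
    if k < 2:
        raise ValidationError("k must be >= 2")
    classes = np.unique(features.y)
    for kk in classes:
        if (features.y == kk).sum() < k:
            raise ValidationError(
                f"class {kk} has fewer than k={k} observations")
    if h_grid is None:
        h_grid = default_h_grid()
    h_grid = np.sort(np.asarray(h_grid, dtype=float))
    if h_grid.size == 0 or np.any(h_grid <= 0):
        raise ValidationError("h_grid must hold positive bandwidths")

    n = features.X.shape[0]
    groups = features.groups
    use_groups = np.unique(groups).size >= k and \
        np.unique(groups).size < n
    if use_groups:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                        random_state=seed)
        splits = list(splitter.split(features.X, features.y, groups))
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                   random_state=seed)
        splits = list(splitter.split(features.X, features.y))

    folds = np.full(n, -1, dtype=int)
    for fi, (_, val) in enumerate(splits):
        folds[val] = fi

    best_h, best_acc, best_pair = None, -1.0, None
    for h in h_grid:
        y_pred = np.empty(n, dtype=features.y.dtype)
        for train, val in splits:
            model = fit_nb(
                FeatureMatrix(features.X[train], features.y[train],
                              features.groups[train],
                              features.offsets[train]), h)
            _, y_pred[val] = predict_batch(model, features.X[val])
        if aggregate == "recording":
            pair = _vote_by_group(features.y, y_pred, features.groups,
                                  classes)
        else:
            pair = (features.y, y_pred)
        acc = float(np.mean(pair[1] == pair[0]))
        if acc > best_acc:  # strict: ties keep the smaller h (grid sorted)
            best_h, best_acc, best_pair = float(h), acc, pair

    report = _report(classes, best_pair[0], best_pair[1], seed=seed,
                     folds=folds, selected_h=best_h)
    return report, best_h
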