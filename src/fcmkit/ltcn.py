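"""Deterministic Moore-Penrose FCM classifier (LTCN-MP style).

A fully connected cognitive network over M feature nodes and N class
nodes.  Training is deterministic and two-staged:

1. *Inner weights* (M x M) are fitted unsupervised by a ridge-regularised
   least-squares self-prediction of the feature block: the hidden
   representation after one propagation step should reproduce the
   inputs.
2. *Output weights* (M x N) are the Moore-Penrose pseudo-inverse
   solution mapping the final hidden representation (after T reasoning
   iterations through the squashing function) onto the one-hot class
   targets.

Features must be normalised to [0, 1].  The model also exposes a
feature-importance vector in [-1, 1], derived from the output weights
(signed per-feature sum over classes, scaled by the maximum absolute
value).  The four squashing parameters ``p`` set the slope/offset of
the logistic used in hidden propagation and of the logit input
transform; their defaults (all 1.0) leave the standard expit/logit
pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

__all__ = ["FeatureTable", "LTCNModel", "read_arff", "fit", "predict"]


@dataclass
class FeatureTable:
    features: np.ndarray  # instances x M, values in [0, 1]
    labels: np.ndarray  # integer class index per instance
    class_names: list[str]
    feature_names: list[str]

    @property
    def onehot(self) -> np.ndarray:
        y = np.zeros((len(self.labels), len(self.class_names)))
        y[np.arange(len(self.labels)), self.labels] = 1.0
        return y


@dataclass
class LTCNModel:
    inner_weights: np.ndarray  # M x M
    output_weights: np.ndarray  # M x N
    importance: np.ndarray  # length M, in [-1, 1]
    T: int = 1
    p: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    folds: list[dict] = field(default_factory=list)
    class_names: list[str] = field(default_factory=list)


def read_arff(path: str | Path) -> FeatureTable:
    """Load an ARFF dataset with numeric features and a nominal class.

    The class attribute is taken as the last nominal column; every
    numeric feature must already be normalised to [0, 1].
    """
    path = Path(path)
    data, meta = scipy_arff.loadarff(str(path))
    frame = pd.DataFrame(data)
    nominal = [n for n, t in zip(meta.names(), meta.types()) if t == "nominal"]
    if not nominal:
        raise ValueError(f"{path.name}: no nominal class attribute found")
    class_col = nominal[-1]
    feature_cols = [n for n in meta.names() if n != class_col]
    non_numeric = [c for c in feature_cols if frame[c].dtype == object]
    if non_numeric:
        raise ValueError(f"{path.name}: non-numeric feature(s) {non_numeric}")
    X = frame[feature_cols].to_numpy(dtype=float)
    if len(X) == 0:
        raise ValueError(f"{path.name}: empty relation")
    for j, name in enumerate(feature_cols):
        lo, hi = X[:, j].min(), X[:, j].max()
        if lo < 0.0 or hi > 1.0:
            raise ValueError(
                f"{path.name}: feature {name!r} outside [0,1] "
                f"(range [{lo:.3g}, {hi:.3g}]); normalise before loading"
            )
    raw = frame[class_col].str.decode("utf-8")
    class_names = sorted(raw.unique())
    labels = raw.map({c: i for i, c in enumerate(class_names)}).to_numpy()
    return FeatureTable(X, labels, class_names, feature_cols)


def _squash(x: np.ndarray, p) -> np.ndarray:
    return expit(p[0] * x + (p[1] - 1.0))


def _logit_in(x: np.ndarray, p) -> np.ndarray:
    clipped = np.clip(x, 1e-6, 1.0 - 1e-6)
    return expit(p[2] * np.log(clipped / (1.0 - clipped)) + (p[3] - 1.0))


def _propagate(X: np.ndarray, W: np.ndarray, T: int, p) -> np.ndarray:
    h = X
    for _ in range(T):
        h = _squash(h @ W, p)
    return h


def _fit_fold(X: np.ndarray, Y: np.ndarray, T: int, p,
              ridge: float) -> tuple[np.ndarray, np.ndarray]:
    M = X.shape[1]
    # unsupervised inner weights: ridge least-squares self-prediction
    gram = X.T @ X + ridge * np.eye(M)
    W_in = np.linalg.solve(gram, X.T @ X)
    H = _propagate(X, W_in, T, p)
    W_out = np.linalg.pinv(H) @ Y
    return W_in, W_out


def fit(table: FeatureTable, T: int = 1,
        p: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
        folds: int = 10, ridge: float = 1e-6,
        seed: int | None = None) -> LTCNModel:
    """Train per stratified fold and aggregate by element-wise mean.

    Requires at least ``folds`` instances per class so stratification
    is possible.  Each fold record stores its weights and training
    accuracy; the aggregate model averages the fold weight matrices.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    counts = np.bincount(table.labels)
    if counts.min() < folds:
        raise ValueError(
            f"stratified {folds}-fold split impossible: smallest class has "
            f"{counts.min()} instance(s)"
        )
    # canonical instance order so fold assignment (and hence the fold-mean
    # aggregate) does not depend on how the rows were stored
    order = np.lexsort(
        tuple(table.features[:, j] for j in range(table.features.shape[1]))
        + (table.labels,)
    )
    X, Y = table.features[order], table.onehot[order]
    labels_sorted = table.labels[order]
    skf = StratifiedKFold(n_splits=folds, shuffle=seed is not None,
                          random_state=seed)
    fold_records, inners, outers = [], [], []
    for train, test in skf.split(X, labels_sorted):
        W_in, W_out = _fit_fold(X[train], Y[train], T, p, ridge)
        model = LTCNModel(W_in, W_out, np.zeros(X.shape[1]), T, p,
                          class_names=table.class_names)
        acc = float(
            (predict(model, X[test]) == labels_sorted[test]).mean()
        )
        fold_records.append({"inner": W_in, "output": W_out, "accuracy": acc})
        inners.append(W_in)
        outers.append(W_out)
    inner = np.mean(inners, axis=0)
    output = np.mean(outers, axis=0)
    signed = output.sum(axis=1)
    scale = np.abs(signed).max()
    importance = signed / scale if scale > 0 else signed
    return LTCNModel(inner, output, importance, T, p, fold_records,
                     table.class_names)


def predict(model: LTCNModel, X: np.ndarray | FeatureTable) -> np.ndarray:
    """Class index per instance (argmax of scores; ties -> lowest index)."""
    feats = X.features if isinstance(X, FeatureTable) else np.asarray(X, float)
    if feats.shape[1] != model.inner_weights.shape[0]:
        raise ValueError(
            f"expected {model.inner_weights.shape[0]} features, "
            f"got {feats.shape[1]}"
        )
    scores = scores_of(model, feats)
    return np.argmax(scores, axis=1)


def scores_of(model: LTCNModel, feats: np.ndarray) -> np.ndarray:
    """Numeric class scores (hidden representation times output weights)."""
    h = _propagate(feats, model.inner_weights, model.T, model.p)
    return h @ model.output_weights
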