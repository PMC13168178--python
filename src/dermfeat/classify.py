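"""MLP classifier and evaluation metrics.

The classifier is a three-hidden-layer perceptron (128/64/32 ReLU units,
each with batch normalization and dropout) with a sigmoid output, trained
with Adam on binary cross-entropy and early stopping on validation
accuracy. Metrics are computed from the confusion counts with malignant as
the positive class; class-weighted variants (which equal accuracy for
recall in the binary case) are reported alongside.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .nn import Adam, BatchNorm, Dense, Dropout, Module, Tensor, autograd as ag


@dataclass
class MLPConfig:
    hidden: tuple[int, ...] = (128, 64, 32)
    dropout: float = 0.3
    learning_rate: float = 0.01
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 15
    seed: int = 0


class MLP(Module):
    def __init__(self, n_features: int, config: MLPConfig | None = None):
        super().__init__()
        self.config = config or MLPConfig()
        self.n_features = n_features
        rng = np.random.default_rng(self.config.seed)
        widths = [n_features, *self.config.hidden]
        self.blocks = []
        for i, (fin, fout) in enumerate(zip(widths[:-1], widths[1:])):
            dense = Dense(fin, fout, rng)
            bn = BatchNorm(fout)
            drop = Dropout(self.config.dropout, rng)
            setattr(self, f"dense{i}", dense)
            setattr(self, f"bn{i}", bn)
            setattr(self, f"drop{i}", drop)
            self.blocks.append((dense, bn, drop))
        self.out = Dense(widths[-1], 1, rng)

    def logits(self, x: Tensor) -> Tensor:
        for dense, bn, drop in self.blocks:
            x = drop(ag.relu(bn(dense(x))))
        return self.out(x)

    def forward(self, x: Tensor) -> Tensor:
        return ag.sigmoid(self.logits(x))


def train_mlp(features: np.ndarray, labels: np.ndarray,
              config: MLPConfig | None = None,
              val_features: np.ndarray | None = None,
              val_labels: np.ndarray | None = None) -> MLP:
    """Train the MLP; early stopping on validation accuracy when a
    validation split is given."""
    cfg = config or MLPConfig()
    X = np.asarray(features, dtype=np.float32)
    y = np.asarray(labels, dtype=np.float32).ravel()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 samples of each class")
    model = MLP(X.shape[1], cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    n = len(X)
    best_acc, best_state, wait = -np.inf, None, 0
    for _ in range(cfg.max_epochs):
        model.train()
        order = rng.permutation(n)
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            logits = model.logits(Tensor(X[idx]))
            loss = ag.bce_with_logits(logits, y[idx])
            model.zero_grad()
            loss.backward()
            opt.step()
        if val_features is not None:
            _, p = predict(model, val_features)
            acc = float(np.mean((p > 0.5) == np.asarray(val_labels)))
            if acc > best_acc:
                best_acc, wait = acc, 0
                best_state = {k: v.copy()
                              for k, v in model.state_arrays().items()}
            else:
                wait += 1
                if wait >= cfg.patience:
                    break
    if best_state is not None:
        model.load_state_arrays(best_state)
    model.eval()
    return model


def predict(model: MLP, features: np.ndarray, threshold: float = 0.5
            ) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels (probability > threshold) and probabilities."""
    X = np.asarray(features, dtype=np.float32)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {X.shape[1] if X.ndim == 2 else '?'} does not "
            f"match the trained width {model.n_features}")
    model.eval()
    with ag.no_grad():
        probs = model(Tensor(X)).data.ravel().astype(float)
    return (probs > threshold).astype(int), probs


# -- metrics ---------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(y_true, y_pred, positive: int = 1) -> ConfusionCounts:
    t = np.asarray(y_true).ravel() == positive
    p = np.asarray(y_pred).ravel() == positive
    return ConfusionCounts(tp=int(np.sum(t & p)), tn=int(np.sum(~t & ~p)),
                           fp=int(np.sum(~t & p)), fn=int(np.sum(t & ~p)))


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator; returning 0")
        return 0.0
    return num / den


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    precision_weighted: float
    recall_weighted: float
    f1_weighted: float
    auc: float | None
    counts: ConfusionCounts

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("accuracy", "precision", "recall", "f1", "precision_weighted",
              "recall_weighted", "f1_weighted", "auc")}
        d["confusion"] = {"tp": self.counts.tp, "tn": self.counts.tn,
                          "fp": self.counts.fp, "fn": self.counts.fn}
        return d


def metrics(y_true, y_pred, probs=None) -> MetricsReport:
    """Accuracy/precision/recall/F1 (malignant = positive) plus
    class-frequency-weighted variants and, when probabilities are given,
    ROC AUC."""
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    c = confusion_counts(y_true, y_pred, positive=1)
    accuracy = (c.tp + c.tn) / c.n
    precision = _safe_div(c.tp, c.tp + c.fp, "precision")
    recall = _safe_div(c.tp, c.tp + c.fn, "recall")
    f1 = _safe_div(2 * c.tp, 2 * c.tp + c.fp + c.fn, "f1")

    # per-class scores weighted by class frequency
    weighted = {"precision": 0.0, "recall": 0.0, "f1": 0.0}
    for cls in (0, 1):
        cc = confusion_counts(y_true, y_pred, positive=cls)
        wgt = np.mean(y_true == cls)
        weighted["precision"] += wgt * _safe_div(cc.tp, cc.tp + cc.fp,
                                                 f"precision[{cls}]")
        weighted["recall"] += wgt * _safe_div(cc.tp, cc.tp + cc.fn,
                                              f"recall[{cls}]")
        weighted["f1"] += wgt * _safe_div(2 * cc.tp, 2 * cc.tp + cc.fp + cc.fn,
                                          f"f1[{cls}]")
    auc = None
    if probs is not None and len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, probs))
    return MetricsReport(accuracy=float(accuracy), precision=float(precision),
                         recall=float(recall), f1=float(f1),
                         precision_weighted=float(weighted["precision"]),
                         recall_weighted=float(weighted["recall"]),
                         f1_weighted=float(weighted["f1"]),
                         auc=auc, counts=c)


def cross_validate(features: np.ndarray, labels: np.ndarray,
                   config: MLPConfig | None = None, folds: int = 5,
                   seed: int = 0) -> dict:
    """Stratified k-fold accuracy of the MLP (mean ± sd over folds)."""
    X = np.asarray(features, dtype=np.float32)
    y = np.asarray(labels).ravel()
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError("each class needs at least `folds` samples")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        model = train_mlp(X[tr], y[tr], config)
        pred, _ = predict(model, X[te])
        accs.append(float(np.mean(pred == y[te])))
    accs = np.array(accs)
    return {"fold_accuracies": accs.tolist(),
            "mean_accuracy": float(accs.mean()),
            "sd_accuracy": float(accs.std())}
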