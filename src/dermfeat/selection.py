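"""Feature selection: SAMI weighted ranking and OFS relevance optimization.

SAMI (self-attention + mutual information) ranks handcrafted features by
running scaled dot-product self-attention over feature tokens with the
pairwise feature-feature mutual-information matrix added to the attention
logits; the attention output norm times the feature-label MI is the final
weight, and the retained count k is picked by 5-fold cross-validated MLP
accuracy (select-k-best).

OFS (optimized feature selection) scores every fused column with
R = sigmoid(α·MI + β·variance − γ·redundancy) (each statistic min-max
normalized across features), keeps the top-k, and tunes (α, β, γ) with an
accuracy-driven update rule δ ← δ + η·ΔAcc·Δδ while k follows an
accept-if-better random search, using validation accuracy of the MLP as the
objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import MLPConfig, predict, train_mlp
from . import classify as classify_mod


# -- mutual information ----------------------------------------------------

@dataclass
class MIEstimator:
    """Plug-in MI on an equal-frequency-binned joint histogram (nats)."""

    n_bins: int = 10

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")

    def discretize(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x).ravel()
        uniq = np.unique(x)
        if len(uniq) <= self.n_bins:
            return np.searchsorted(uniq, x)
        qs = np.quantile(x, np.linspace(0, 1, self.n_bins + 1)[1:-1])
        return np.searchsorted(qs, x, side="right")


def mutual_information_from_joint(P: np.ndarray) -> float:
    """MI in nats of a joint probability table (closed-form summation)."""
    P = np.asarray(P, dtype=float)
    px = P.sum(axis=1, keepdims=True)
    py = P.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = P * np.log(P / (px * py))
    return float(np.nansum(terms))


def mutual_information(x: np.ndarray, y: np.ndarray,
                       estimator: MIEstimator | None = None) -> float:
    """Symmetric plug-in mutual information between two samples, in nats."""
    est = estimator or MIEstimator()
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 10:
        raise ValueError("need at least 10 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant variable; MI = 0")
        return 0.0
    xi = est.discretize(x)
    yi = est.discretize(y)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    return max(mutual_information_from_joint(joint / joint.sum()), 0.0)


def mi_matrix(X: np.ndarray, estimator: MIEstimator | None = None
              ) -> np.ndarray:
    """Symmetric pairwise feature-feature MI matrix."""
    est = estimator or MIEstimator()
    d = X.shape[1]
    M = np.zeros((d, d))
    codes = [est.discretize(X[:, j]) for j in range(d)]
    for i in range(d):
        for j in range(i, d):
            joint = np.zeros((codes[i].max() + 1, codes[j].max() + 1))
            np.add.at(joint, (codes[i], codes[j]), 1.0)
            M[i, j] = M[j, i] = max(
                mutual_information_from_joint(joint / joint.sum()), 0.0)
    return M


# -- SAMI ------------------------------------------------------------------

@dataclass
class AttentionProjections:
    """Seeded random orthogonal projections for Q, K, V."""

    w_q: np.ndarray
    w_k: np.ndarray
    w_v: np.ndarray
    d_k: int

    @classmethod
    def create(cls, n_samples: int, d_k: int | None = None, seed: int = 0):
        d_k = min(64, n_samples) if d_k is None else d_k
        if d_k > n_samples:
            raise ValueError("projection width d_k cannot exceed n_samples")
        rng = np.random.default_rng(seed)

        def ortho():
            q, _ = np.linalg.qr(rng.normal(size=(n_samples, d_k)))
            return q

        return cls(w_q=ortho(), w_k=ortho(), w_v=ortho(), d_k=d_k)


def _softmax_rows(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def sami_scores(features: np.ndarray, labels: np.ndarray,
                projections: AttentionProjections | None = None,
                estimator: MIEstimator | None = None,
                return_details: bool = False):
    """Per-feature SAMI weight.

    Features are tokens with their (standardized) sample vector as the
    embedding. Attention logits QKᵀ/√d_k are biased additively by the
    pairwise feature MI matrix before the row softmax; the output norm
    ‖O_i‖₂ is multiplied by MI(f_i, labels) to combine attention weighting
    with target-relevance ranking.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need an (n, d) matrix with d >= 2")
    n, d = X.shape
    est = estimator or MIEstimator()
    proj = projections or AttentionProjections.create(n)
    if proj.w_q.shape[0] != n:
        raise ValueError("projection shape does not match sample count")
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Xz = (X - X.mean(axis=0)) / std
    E = Xz.T  # feature tokens, (d, n)
    Q, K, V = E @ proj.w_q, E @ proj.w_k, E @ proj.w_v
    M = mi_matrix(Xz, est)
    logits = Q @ K.T / np.sqrt(proj.d_k) + M
    A = _softmax_rows(logits)
    O = A @ V
    target_mi = np.array([mutual_information(Xz[:, j], labels, est)
                          for j in range(d)])
    scores = np.linalg.norm(O, axis=1) * target_mi
    if return_details:
        return scores, {"attention": A, "mi_matrix": M,
                        "target_mi": target_mi}
    return scores


@dataclass
class SAMISelection:
    scores: np.ndarray
    ranks: np.ndarray              # feature indices, best first
    chosen_k: int
    cv_accuracies: dict[int, float]
    selected: list                 # names (or indices) of the retained set


def select_k_best(features: np.ndarray, labels: np.ndarray,
                  scores: np.ndarray, k_grid: list[int], cv: int = 5,
                  seed: int = 0, mlp_config: MLPConfig | None = None,
                  feature_names: list[str] | None = None) -> SAMISelection:
    """Choose k by stratified cross-validated MLP accuracy on the top-k
    features (ties broken toward smaller k)."""
    X = np.asarray(features, dtype=float)
    d = X.shape[1]
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ValueError("empty k grid")
    if k_grid[0] < 2 or k_grid[-1] > d:
        raise ValueError("k grid must lie within [2, d]")
    names = list(feature_names) if feature_names is not None else list(range(d))
    order = np.argsort(-np.asarray(scores), kind="stable")
    cfg = mlp_config or MLPConfig(max_epochs=30, patience=10, seed=seed)
    accs: dict[int, float] = {}
    for k in k_grid:
        cols = order[:k]
        res = classify_mod.cross_validate(X[:, cols], labels, cfg,
                                          folds=cv, seed=seed)
        accs[k] = res["mean_accuracy"]
    chosen = max(k_grid, key=lambda k: (accs[k], -k))
    return SAMISelection(scores=np.asarray(scores), ranks=order,
                         chosen_k=chosen, cv_accuracies=accs,
                         selected=[names[i] for i in order[:chosen]])


# -- fusion ----------------------------------------------------------------

@dataclass
class FusedFeatures:
    data: pd.DataFrame             # standardized columns
    provenance: list[str]          # "handcrafted" or "deep" per column


def fuse(selected_hand: pd.DataFrame, deep: pd.DataFrame,
         train_mask: np.ndarray | None = None) -> FusedFeatures:
    """Concatenate SAMI-retained handcrafted columns with deep features.

    Sample ids (indexes) must align. Every column is z-scored with
    statistics from the training rows (all rows when no mask is given).
    """
    if len(selected_hand) != len(deep):
        raise ValueError("row count mismatch between feature blocks")
    if not selected_hand.index.equals(deep.index):
        raise ValueError("sample id mismatch between feature blocks")
    fused = pd.concat([selected_hand, deep], axis=1)
    if fused.columns.duplicated().any():
        raise ValueError("duplicate column names after fusion")
    mask = (np.ones(len(fused), dtype=bool) if train_mask is None
            else np.asarray(train_mask, dtype=bool))
    stats = fused.loc[mask]
    mu = stats.mean(axis=0)
    sd = stats.std(axis=0, ddof=0).replace(0.0, 1.0)
    data = (fused - mu) / sd
    provenance = (["handcrafted"] * selected_hand.shape[1]
                  + ["deep"] * deep.shape[1])
    return FusedFeatures(data=data, provenance=provenance)


# -- OFS -------------------------------------------------------------------

def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi - lo < 1e-12:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class RelevanceStats:
    """Per-feature MI, variance and redundancy, min-max normalized."""

    mi: np.ndarray
    variance: np.ndarray
    redundancy: np.ndarray


def compute_relevance_stats(features: np.ndarray, labels: np.ndarray,
                            estimator: MIEstimator | None = None
                            ) -> RelevanceStats:
    X = np.asarray(features, dtype=float)
    d = X.shape[1]
    if d < 2:
        raise ValueError("need at least 2 features")
    est = estimator or MIEstimator()
    mi = np.array([mutual_information(X[:, j], labels, est)
                   for j in range(d)])
    var = X.var(axis=0)
    C = np.corrcoef(X, rowvar=False)
    C = np.nan_to_num(C, nan=0.0)
    np.fill_diagonal(C, 0.0)
    rd = np.abs(C).max(axis=1)
    return RelevanceStats(mi=_minmax(mi), variance=_minmax(var),
                          redundancy=_minmax(rd))


def relevance_scores(features: np.ndarray, labels: np.ndarray, alpha: float,
                     beta: float, gamma: float,
                     stats: RelevanceStats | None = None) -> np.ndarray:
    """R_i = sigmoid(α·MI_i + β·v_i − γ·Rd_i) with normalized statistics."""
    for name, v in (("alpha", alpha), ("beta", beta), ("gamma", gamma)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    s = stats or compute_relevance_stats(features, labels)
    return _sigmoid(alpha * s.mi + beta * s.variance - gamma * s.redundancy)


def update_param(delta_t: float, delta_prev: float, acc_t: float,
                 acc_prev: float, eta: float = 0.01) -> float:
    """δ_{t+1} = clip(δ_t + η·ΔAcc·Δδ, 0, 1)."""
    return float(np.clip(delta_t + eta * (acc_t - acc_prev)
                         * (delta_t - delta_prev), 0.0, 1.0))


@dataclass
class OFSResult:
    alpha: float
    beta: float
    gamma: float
    k: int
    selected: list
    val_accuracy: float
    test_accuracy: float
    history: list          # per-iteration validation accuracy
    trajectory: list       # per-iteration (alpha, beta, gamma, k)


def ofs_search(fused: pd.DataFrame, labels: np.ndarray, splits: dict,
               n_iter: int = 50, patience: int = 15, seed: int = 0,
               mlp_config: MLPConfig | None = None,
               estimator: MIEstimator | None = None) -> OFSResult:
    """Random-search/update-rule optimization of (α, β, γ, k).

    ``splits`` maps ``train``/``val``/``test`` to row index arrays. The
    relevance statistics are computed once on the training split; each
    iteration trains the MLP on the top-k columns and scores validation
    accuracy (the objective). α, β, γ follow the ΔAcc·Δδ update rule (the
    first step uses a random perturbation as Δδ); k proposals are accepted
    greedily on validation-accuracy improvement. Stops after ``n_iter``
    iterations or ``patience`` without improvement, then reports the test
    accuracy of the best configuration.
    """
    X = fused.to_numpy(dtype=float)
    y = np.asarray(labels).ravel()
    d = X.shape[1]
    tr, va, te = (np.asarray(splits[s]) for s in ("train", "val", "test"))
    rng = np.random.default_rng(seed)
    cfg = mlp_config or MLPConfig(max_epochs=30, patience=10, seed=seed)
    stats = compute_relevance_stats(X[tr], y[tr], estimator)

    params = rng.uniform(0.0, 1.0, size=3)  # alpha, beta, gamma
    prev_params = np.clip(params + rng.uniform(-0.1, 0.1, size=3), 0.0, 1.0)
    k_curr = int(rng.integers(2, d + 1))
    acc_prev = None
    best = None
    history: list[float] = []
    trajectory: list[tuple] = []
    wait = 0
    for t in range(n_iter):
        k_trial = k_curr if t == 0 else int(rng.integers(2, d + 1))
        if k_trial > d:
            warnings.warn("k exceeds feature count; clamping")
            k_trial = d
        R = _sigmoid(params[0] * stats.mi + params[1] * stats.variance
                     - params[2] * stats.redundancy)
        cols = np.argsort(-R, kind="stable")[:k_trial]
        model = train_mlp(X[tr][:, cols], y[tr], cfg)
        pred, _ = predict(model, X[va][:, cols])
        acc = float(np.mean(pred == y[va]))
        history.append(acc)
        trajectory.append((params[0], params[1], params[2], k_trial))
        if best is None or acc > best["acc"]:
            best = {"acc": acc, "params": params.copy(), "k": k_trial,
                    "cols": cols.copy()}
            k_curr = k_trial
            wait = 0
        else:
            wait += 1
            if wait >= patience:
                break
        if acc_prev is not None:
            new = np.array([update_param(params[i], prev_params[i],
                                         acc, acc_prev) for i in range(3)])
            prev_params, params = params, new
        acc_prev = acc
    cols = best["cols"]
    model = train_mlp(X[tr][:, cols], y[tr], cfg)
    pred, _ = predict(model, X[te][:, cols])
    test_acc = float(np.mean(pred == y[te]))
    names = list(fused.columns)
    a, b, g = best["params"]
    return OFSResult(alpha=float(a), beta=float(b), gamma=float(g),
                     k=int(best["k"]), selected=[names[i] for i in cols],
                     val_accuracy=float(best["acc"]),
                     test_accuracy=test_acc, history=history,
                     trajectory=trajectory)
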