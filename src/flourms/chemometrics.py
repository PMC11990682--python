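"""Two-class discrimination: PCA, PLS-DA, VIP, bootstrap, permutation, ROC.

The feature matrix is pretreated with log10(x+1) followed by per-feature
autoscaling (mean-centre, unit variance), then:

* PCA (SVD) gives an unsupervised view of sample structure;
* a NIPALS PLS1 model with y in {0,1} gives the supervised axis, its
  goodness of fit R2Y and cross-validated predictability Q2;
* VIP scores rank features, with bootstrap aggregation (stratified
  resampling with replacement, refit, average) stabilising the ranking;
* a permutation test (shuffle y, refit, record R2Y/Q2) guards against
  over-fitting: the model is valid only when every permuted value falls
  strictly below the original;
* ROC/AUC on cross-validated predicted scores measures class separation
  without the optimism of resubstitution.

VIP is normalised so that the mean squared VIP equals 1; features above
the conventional cut-off of 1.0 are "selected".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ChemometricsConfig",
    "PretreatTransform",
    "PcaResult",
    "PlsdaModel",
    "ValidationReport",
    "pretreat",
    "pca",
    "plsda_fit",
    "vip",
    "bootstrap_vip",
    "cross_validated_q2",
    "permutation_test",
    "roc_auc",
    "run_discrimination",
]


@dataclass(frozen=True)
class ChemometricsConfig:
    n_components: int = 2
    vip_cutoff: float = 1.0
    n_bootstrap: int = 100
    n_permutations: int = 100
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("need >= 1 component")
        if self.cv_folds < 2:
            raise ValueError("need >= 2 CV folds")
        if self.vip_cutoff <= 0:
            raise ValueError("VIP cutoff must be positive")


# ---------------------------------------------------------------------------
# pretreatment
# ---------------------------------------------------------------------------

@dataclass
class PretreatTransform:
    """log10(x+1) + autoscale, reusable on held-out rows."""

    kept: np.ndarray      # indices of non-constant features
    mean: np.ndarray
    sd: np.ndarray
    dropped: np.ndarray   # indices of constant features

    def apply(self, X: np.ndarray) -> np.ndarray:
        Xl = np.log10(np.asarray(X, dtype=float)[:, self.kept] + 1.0)
        return (Xl - self.mean) / self.sd


def pretreat(X: np.ndarray) -> Tuple[np.ndarray, PretreatTransform]:
    """Scale a samples x features area matrix; drops zero-variance features."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 features")
    if not np.any(X):
        raise ValueError("all-zero matrix")
    Xl = np.log10(X + 1.0)
    sd = Xl.std(axis=0, ddof=0)
    # constant up to floating-point residue counts as constant
    tol = 1e-10 * np.maximum(1.0, np.abs(Xl).max(axis=0))
    kept = np.flatnonzero(sd > tol)
    dropped = np.flatnonzero(sd <= tol)
    if kept.size < 2:
        raise ValueError("fewer than 2 non-constant features")
    tf = PretreatTransform(kept, Xl[:, kept].mean(axis=0), sd[kept], dropped)
    return tf.apply(X), tf


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_pct: np.ndarray


def pca(X: np.ndarray, n_components: int = 2) -> PcaResult:
    """PCA by SVD of the (already pretreated) matrix."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size else 0
    k = min(n_components, rank)
    expl = (S ** 2) / np.sum(S ** 2) * 100.0
    # sign convention: largest-|loading| element positive, for determinism
    V = Vt[:k].T
    signs = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    return PcaResult(
        scores=(U[:, :k] * S[:k]) * signs,
        loadings=V * signs,
        explained_variance_pct=expl[:k],
    )


# ---------------------------------------------------------------------------
# PLS-DA (NIPALS PLS1)
# ---------------------------------------------------------------------------

@dataclass
class PlsdaModel:
    weights: np.ndarray      # (p, A) x-weights, unit norm per component
    x_loadings: np.ndarray   # (p, A)
    scores: np.ndarray       # (n, A)
    y_loadings: np.ndarray   # (A,)
    y_mean: float
    x_mean: np.ndarray
    coef: np.ndarray         # (p,) regression vector on centred X
    r2y: float
    ssy: np.ndarray          # (A,) y-variance explained per component

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.y_mean + (np.asarray(X, dtype=float) - self.x_mean) @ self.coef


def plsda_fit(X: np.ndarray, y: np.ndarray, n_components: int = 2) -> PlsdaModel:
    """NIPALS PLS1 with X-deflation; y coded {0,1} and centred internally.

    For a single y the NIPALS weight step is closed-form (w = X'y/|X'y|),
    so each component is one pass: scores t = Xw, loadings p = X't/t't,
    y-loading q = y't/t't, deflate X. R2Y = 1 - RSS/TSS of the fitted y.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("y contains a single class")
    n, p = X.shape
    A = min(n_components, n - 1, p)

    y_mean = float(y.mean())
    yc = y - y_mean
    x_mean = X.mean(axis=0)
    Xd = X - x_mean
    yd = yc.copy()

    W = np.zeros((p, A))
    P = np.zeros((p, A))
    T = np.zeros((n, A))
    q = np.zeros(A)
    ssy = np.zeros(A)

    for a in range(A):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            A = a
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-14:
            A = a
            break
        pl = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd -= np.outer(t, pl)
        yd = yd - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pl, t, qa
        ssy[a] = qa * qa * tt

    W, P, T, q, ssy = W[:, :A], P[:, :A], T[:, :A], q[:A], ssy[:A]
    # regression vector: b = W (P'W)^-1 q
    coef = W @ np.linalg.solve(P.T @ W, q) if A else np.zeros(p)
    fitted = y_mean + (X - x_mean) @ coef
    tss = float(yc @ yc)
    r2y = 1.0 - float(np.sum((y - fitted) ** 2)) / tss if tss > 0 else 0.0
    return PlsdaModel(W, P, T, q, y_mean, x_mean, coef, min(max(r2y, 0.0), 1.0), ssy)


def vip(model: PlsdaModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / |w_a|)^2 / sum_a SSY_a ); with
    unit-norm weights the inner ratio is w_ja^2. Mean squared VIP is
    exactly 1.
    """
    W, ssy = model.weights, model.ssy
    p = W.shape[0]
    denom = float(ssy.sum())
    if denom <= 0:
        return np.zeros(p)
    wnorm2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    return np.sqrt(p * (wnorm2 @ ssy) / denom)


# ---------------------------------------------------------------------------
# resampling machinery
# ---------------------------------------------------------------------------

def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> List[np.ndarray]:
    folds: List[List[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % k].append(j)
    return [np.sort(np.array(f)) for f in folds if len(f)]


def cross_validated_q2(
    X: np.ndarray, y: np.ndarray, config: ChemometricsConfig,
    rng: Optional[np.random.Generator] = None,
    return_scores: bool = False,
):
    """Stratified k-fold Q2 = 1 - PRESS/TSS, fold models fit on training
    rows only. Optionally also returns the out-of-fold predicted scores."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = rng or np.random.default_rng(config.seed)
    counts = [np.sum(y == c) for c in np.unique(y)]
    if min(counts) < 2:
        raise ValueError("each class needs >= 2 samples for CV")
    k = min(config.cv_folds, min(counts))
    folds = _stratified_folds(y, k, rng)
    pred = np.empty_like(y)
    for test in folds:
        train = np.setdiff1d(np.arange(len(y)), test)
        m = plsda_fit(X[train], y[train], config.n_components)
        pred[test] = m.predict(X[test])
    press = float(np.sum((y - pred) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - press / tss if tss > 0 else 0.0
    return (q2, pred) if return_scores else q2


def bootstrap_vip(
    X: np.ndarray, y: np.ndarray, config: ChemometricsConfig,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Mean VIP over stratified bootstrap refits (original class sizes,
    sampling with replacement within class). Seeded and reproducible."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = rng or np.random.default_rng(config.seed)
    class_idx = [np.flatnonzero(y == c) for c in np.unique(y)]
    if any(len(ix) < 2 for ix in class_idx):
        raise ValueError("each class needs >= 2 samples to bootstrap")
    if config.n_bootstrap < 1:
        raise ValueError("need >= 1 bootstrap replicate")
    total = np.zeros(X.shape[1])
    for _ in range(config.n_bootstrap):
        take = np.concatenate([rng.choice(ix, size=len(ix), replace=True)
                               for ix in class_idx])
        m = plsda_fit(X[take], y[take], config.n_components)
        total += vip(m)
    return total / config.n_bootstrap


def permutation_test(
    X: np.ndarray, y: np.ndarray, config: ChemometricsConfig,
    r2y_original: float, q2_original: float,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, np.ndarray, bool]:
    """Refit under shuffled labels n_permutations times.

    Returns (permuted R2Y, permuted Q2, valid) where valid requires every
    permuted value strictly below its original."""
    if config.n_permutations < 1:
        raise ValueError("need >= 1 permutation")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = rng or np.random.default_rng(config.seed)
    r2s = np.empty(config.n_permutations)
    q2s = np.empty(config.n_permutations)
    for i in range(config.n_permutations):
        yp = rng.permutation(y)
        r2s[i] = plsda_fit(X, yp, config.n_components).r2y
        q2s[i] = cross_validated_q2(X, yp, config, rng)
    valid = bool(np.all(r2s < r2y_original) and np.all(q2s < q2_original))
    return r2s, q2s, valid


def roc_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney U / (n1*n0)), ties mid-ranked."""
    y = np.asarray(y).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("AUC needs exactly two classes")
    pos = y == classes.max()
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)
    u = float(ranks[pos].sum()) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    r2y: float
    q2: float
    permuted_r2y: np.ndarray
    permuted_q2: np.ndarray
    valid: bool
    auc: float
    accuracy_pct: float
    vip_mean: np.ndarray
    selected_features: np.ndarray      # indices into the ORIGINAL feature set
    pca_explained_pct: np.ndarray
    cv_scores: np.ndarray = field(default_factory=lambda: np.empty(0))
    kept_features: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def to_dict(self) -> Dict:
        return {
            "r2y": self.r2y,
            "q2": self.q2,
            "permuted_r2y": self.permuted_r2y.tolist(),
            "permuted_q2": self.permuted_q2.tolist(),
            "valid": self.valid,
            "auc": self.auc,
            "accuracy_pct": self.accuracy_pct,
            "vip_mean": self.vip_mean.tolist(),
            "selected_features": self.selected_features.tolist(),
            "pca_explained_pct": self.pca_explained_pct.tolist(),
            "cv_scores": self.cv_scores.tolist(),
            "kept_features": self.kept_features.tolist(),
        }


def classification_accuracy_pct(scores: np.ndarray, y: np.ndarray) -> float:
    """Percent correctly classified at the accuracy-optimal score threshold."""
    y = np.asarray(y, dtype=float).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    pos = y == y.max()
    cuts = np.concatenate(([-np.inf], np.unique(scores)))
    best = 0.0
    for c in cuts:
        acc = float(np.mean((scores > c) == pos))
        best = max(best, acc, float(np.mean((scores <= c) == pos)))
    return 100.0 * best


def run_discrimination(
    X_raw: np.ndarray, labels: List[str], config: ChemometricsConfig = ChemometricsConfig(),
) -> ValidationReport:
    """The full two-class pipeline on a raw area matrix.

    Pretreat, PCA, PLS-DA fit, CV Q2 + out-of-fold scores, bootstrap VIP,
    permutation validation, ROC/AUC and threshold accuracy. Deterministic
    given config.seed.
    """
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two classes, got {uniq}")
    y = np.array([uniq.index(l) for l in labels], dtype=float)
    Xs, tf = pretreat(np.asarray(X_raw, dtype=float))

    rng = np.random.default_rng(config.seed)
    model = plsda_fit(Xs, y, config.n_components)
    q2, cv_scores = cross_validated_q2(Xs, y, config, rng, return_scores=True)
    vip_mean = bootstrap_vip(Xs, y, config, rng)
    perm_r2, perm_q2, valid = permutation_test(Xs, y, config, model.r2y, q2, rng)
    auc = roc_auc(cv_scores, y)
    acc = classification_accuracy_pct(cv_scores, y)
    p = pca(Xs, config.n_components)
    return ValidationReport(
        r2y=model.r2y, q2=q2, permuted_r2y=perm_r2, permuted_q2=perm_q2,
        valid=valid, auc=auc, accuracy_pct=acc, vip_mean=vip_mean,
        selected_features=tf.kept[np.flatnonzero(vip_mean > config.vip_cutoff)],
        pca_explained_pct=p.explained_variance_pct, cv_scores=cv_scores,
        kept_features=tf.kept,
    )
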