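"""Partial least squares discriminant analysis of dying vs living cells.

The classifier is PLS1 regression on a binary class indicator (living = 0,
dying = 1) fit by NIPALS after column centering and, by default, unit-variance
(auto)scaling — the chemometrics convention.  With a single response the
NIPALS components are closed-form:

    w_a = X_a' y_a / ||X_a' y_a||          (unit-norm weight)
    t_a = X_a w_a                           (score)
    p_a = X_a' t_a / (t_a' t_a)             (loading)
    q_a = y_a' t_a / (t_a' t_a)             (response loading)
    X_{a+1} = X_a - t_a p_a',  y_{a+1} = y_a - q_a t_a

and the per-feature discriminant coefficients in the scaled space are
beta = W (P'W)^{-1} q.  Successive scores are mutually orthogonal.

On top of the estimator the module provides the inference tooling used to
extract a sparse signaling code: a tie-aware ROC/AUC, three cross-validation
fold schemes (random, venetian blind, contiguous block), a label-permutation
null for beta, VIP scores, top-k / VIP>1 feature selection with an agreement
report, and the unscaled combined score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .events import EventMatrix

__all__ = [
    "PLSDA", "PermutationResult", "fit_plsda", "predict_scores", "roc_auc",
    "cross_validate", "permutation_test_beta", "vip_scores",
    "select_features", "combined_score",
]


class PLSDA(BaseEstimator, ClassifierMixin):
    """Two-class PLS discriminant analysis.

    Parameters
    ----------
    n_components : int, default 2
        Number of latent variables.
    scale : bool, default True
        Autoscale columns to unit variance (sample sd, ddof=1) before fitting.
        The returned ``coef_`` lives in the scaled space.

    Attributes
    ----------
    classes_ : (2,) array — sorted class labels; the larger codes as 1.
    x_mean_, x_std_ : per-feature centering/scaling constants.
    x_weights_ : (p, A) unit-norm weight vectors W.
    x_loadings_ : (p, A) loadings P.
    y_loadings_ : (A,) response loadings q.
    x_scores_ : (n, A) training scores T (mutually orthogonal columns).
    coef_ : (p,) discriminant coefficient vector beta in the scaled space.
    intercept_ : float — training mean of the 0/1 indicator.
    """

    def __init__(self, n_components: int = 2, scale: bool = True):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"PLSDA requires exactly two classes, got {len(self.classes_)}")
        y01 = (y == self.classes_[1]).astype(float)
        n, p = X.shape
        if p < self.n_components:
            raise ValueError("more latent variables than features")

        self.x_mean_ = X.mean(axis=0)
        if self.scale:
            sd = X.std(axis=0, ddof=1)
            degenerate = sd <= 1e-12 * np.maximum(1.0, np.abs(self.x_mean_))
            if np.any(degenerate):
                bad = int(np.argmax(degenerate))
                raise ValueError(
                    f"constant feature (column {bad}) cannot be autoscaled")
            self.x_std_ = sd
        else:
            self.x_std_ = np.ones(p)
        Xc = (X - self.x_mean_) / self.x_std_
        self.intercept_ = float(y01.mean())
        yc = y01 - self.intercept_

        A = self.n_components
        W = np.empty((p, A))
        P = np.empty((p, A))
        q = np.empty(A)
        T = np.empty((n, A))
        Xd, yd = Xc.copy(), yc.copy()
        for a in range(A):
            w = Xd.T @ yd
            nw = np.linalg.norm(w)
            if nw < 1e-300:
                raise ValueError(
                    f"response variance exhausted at component {a + 1}")
            w /= nw
            t = Xd @ w
            tt = float(t @ t)
            pa = Xd.T @ t / tt
            qa = float(yd @ t / tt)
            Xd -= np.outer(t, pa)
            yd -= qa * t
            W[:, a], P[:, a], q[a], T[:, a] = w, pa, qa, t

        self.x_weights_, self.x_loadings_, self.y_loadings_ = W, P, q
        self.x_scores_ = T
        self.coef_ = W @ np.linalg.solve(P.T @ W, q)
        self.n_features_in_ = p
        return self

    def decision_function(self, X) -> np.ndarray:
        """Continuous discriminant score toward the 0/1 class coding."""
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was fit with "
                f"{self.n_features_in_}")
        return ((X - self.x_mean_) / self.x_std_) @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        score = self.decision_function(X)
        return np.where(score >= 0.5, self.classes_[1], self.classes_[0])

    def score_orthogonality(self) -> float:
        """max |t_a . t_b| / (||t_a|| ||t_b||) over component pairs a != b."""
        check_is_fitted(self, "x_scores_")
        T = self.x_scores_
        G = T.T @ T
        norms = np.sqrt(np.diag(G))
        C = np.abs(G) / np.outer(norms, norms)
        np.fill_diagonal(C, 0.0)
        return float(C.max(initial=0.0))


def fit_plsda(X, y, n_lv: int = 2, autoscale: bool = True) -> PLSDA:
    return PLSDA(n_components=n_lv, scale=autoscale).fit(X, y)


def predict_scores(model: PLSDA, X) -> np.ndarray:
    return model.decision_function(X)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC by the normalized Mann–Whitney U (ties count 1/2) plus the ROC
    curve evaluated at every distinct threshold.

    Returns ``(auc, fpr, tpr)``; the curve runs from (0, 0) to (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("roc_auc requires both classes present")
    pos = labels == classes[1]
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)  # average ranks: ties count 1/2
    auc = (ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    order = np.argsort(-scores, kind="mergesort")
    s_sorted, p_sorted = scores[order], pos[order]
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tp = np.cumsum(p_sorted)[distinct]
    fp = np.cumsum(~p_sorted)[distinct]
    tpr = np.r_[0.0, tp / n1]
    fpr = np.r_[0.0, fp / n0]
    return float(auc), fpr, tpr


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _folds(n: int, n_folds: int, scheme: str, rng: np.random.Generator):
    idx = np.arange(n)
    if scheme == "random":
        sh = rng.permutation(n)
        return [np.sort(sh[k::n_folds]) for k in range(n_folds)]
    if scheme == "venetian":
        # fold k takes every n_folds-th event starting at offset k, file order
        return [idx[k::n_folds] for k in range(n_folds)]
    if scheme == "block":
        bounds = np.linspace(0, n, n_folds + 1).astype(int)
        return [idx[bounds[k]:bounds[k + 1]] for k in range(n_folds)]
    raise ValueError(f"unknown CV scheme {scheme!r}")


def cross_validate(X, y, n_lv: int = 2, scheme: str = "random",
                   holdout: float = 0.10, repeats: int = 1,
                   seed: int = 0, autoscale: bool = True) -> dict:
    """Repeatedly withhold ``holdout`` of the events and refit.

    ``scheme`` is one of ``random`` (shuffled folds), ``venetian`` (every
    k-th event at successive offsets, in file order) or ``block`` (contiguous
    segments).  Held-out scores are pooled for a single cross-validated ROC.
    Folds whose training half lacks a class are skipped with a warning and
    recorded.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    n_folds = int(round(1.0 / holdout))
    rng = np.random.default_rng(seed)
    fold_aucs, skipped = [], []
    pooled_scores = np.full(n, np.nan)
    for rep in range(repeats):
        for k, test_idx in enumerate(_folds(n, n_folds, scheme, rng)):
            train = np.setdiff1d(np.arange(n), test_idx)
            if len(np.unique(y[train])) < 2:
                warnings.warn(f"fold {k}: single-class training set, skipped")
                skipped.append((rep, k))
                continue
            m = PLSDA(n_components=n_lv, scale=autoscale).fit(X[train], y[train])
            s = m.decision_function(X[test_idx])
            pooled_scores[test_idx] = s
            if len(np.unique(y[test_idx])) == 2:
                fold_aucs.append(roc_auc(s, y[test_idx])[0])
    have = ~np.isnan(pooled_scores)
    if have.any() and len(np.unique(y[have])) == 2:
        pooled_auc = roc_auc(pooled_scores[have], y[have])[0]
    else:
        pooled_auc = float("nan")  # skipped folds left one pooled class
    return {"fold_aucs": np.array(fold_aucs), "pooled_auc": pooled_auc,
            "pooled_scores": pooled_scores, "skipped": skipped,
            "scheme": scheme, "n_folds": n_folds}


# ---------------------------------------------------------------------------
# permutation null for beta
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Label-permutation null for the discriminant coefficients.

    ``p_two_sided[j] = (1 + #{b : |beta_bj| >= |beta_j|}) / (B + 1)`` — the
    +1 correction keeps p-values in [1/(B+1), 1].  ``null_sd`` is the
    per-feature standard deviation of the null around zero (the error bars
    drawn on coefficient plots).
    """

    observed_beta: np.ndarray
    null_beta: np.ndarray
    p_two_sided: np.ndarray
    B: int
    seed: int

    @property
    def null_sd(self) -> np.ndarray:
        return self.null_beta.std(axis=0, ddof=1)


def permutation_test_beta(X, y, n_lv: int = 2, B: int = 10_000,
                          seed: int = 0, autoscale: bool = True) -> PermutationResult:
    """Refit on uniformly permuted labels B times to build a null for beta."""
    if B < 100:
        raise ValueError("B must be >= 100 for a usable null tail")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    obs = PLSDA(n_components=n_lv, scale=autoscale).fit(X, y).coef_
    rng = np.random.default_rng(seed)
    null = np.empty((B, X.shape[1]))
    for b in range(B):
        yb = rng.permutation(y)
        null[b] = PLSDA(n_components=n_lv, scale=autoscale).fit(X, yb).coef_
    p = (1.0 + (np.abs(null) >= np.abs(obs)).sum(axis=0)) / (B + 1.0)
    return PermutationResult(obs, null, p, B, seed)


# ---------------------------------------------------------------------------
# VIP and selection
# ---------------------------------------------------------------------------

def vip_scores(model: PLSDA) -> np.ndarray:
    """Variable Importance in Projection.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a ) with
    SSY_a = q_a^2 (t_a . t_a); mean squared VIP over features is exactly 1,
    so VIP > 1 marks above-average importance.
    """
    check_is_fitted(model, "x_weights_")
    W, T, q = model.x_weights_, model.x_scores_, model.y_loadings_
    p = W.shape[0]
    ssy = q ** 2 * np.einsum("ia,ia->a", T, T)
    wnorm2 = (W / np.linalg.norm(W, axis=0)) ** 2
    return np.sqrt(p * (wnorm2 @ ssy) / ssy.sum())


@dataclass
class FeatureSelection:
    by_permutation: list[str]
    by_vip: list[str]
    agreement: bool


def select_features(perm: PermutationResult, vip: np.ndarray,
                    feature_names: list[str], k: int = 4) -> FeatureSelection:
    """Top-k features by permutation p (ties by |beta|, then channel order),
    and the VIP > 1 set; reports whether the two selectors agree exactly."""
    p_feat = len(feature_names)
    if k > p_feat:
        raise ValueError(f"k={k} exceeds feature count {p_feat}")
    order = sorted(range(p_feat),
                   key=lambda j: (perm.p_two_sided[j],
                                  -abs(perm.observed_beta[j]), j))
    top = [feature_names[j] for j in order[:k]]
    vip_set = [feature_names[j] for j in range(p_feat) if vip[j] > 1.0]
    return FeatureSelection(top, vip_set, set(top) == set(vip_set))


def combined_score(events: EventMatrix | np.ndarray, features: list[str],
                   signs: list[int],
                   feature_names: list[str] | None = None) -> np.ndarray:
    """Sign-weighted sum of the selected channels WITHOUT rescaling.

    score_i = sum_j sign_j * x_ij on the transformed channel values — the
    channels are deliberately not z-scored, so each marker contributes on its
    native transformed scale.  ``signs`` come from sign(beta).
    """
    if len(features) != len(signs) or any(s not in (+1, -1) for s in signs):
        raise ValueError("signs must be +1/-1, one per feature")
    if isinstance(events, EventMatrix):
        cols = [events.column(f) for f in features]
    else:
        X = np.asarray(events, dtype=float)
        if feature_names is None:
            raise ValueError("feature_names required with a bare array")
        missing = [f for f in features if f not in feature_names]
        if missing:
            raise KeyError(f"features not present: {missing}")
        cols = [X[:, feature_names.index(f)] for f in features]
    return sum(s * c for s, c in zip(signs, cols))
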