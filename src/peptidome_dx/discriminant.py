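"""PLS-DA refinement, VIP ranking, cross-validation and PCA checks.

Partial least squares discriminant analysis (PLS-DA) is fit by the NIPALS
algorithm on autoscaled features against a centered {0,1} class coding.
Feature importance uses the variable importance in projection (VIP)
score,

    VIP_j = sqrt( p * sum_a [ SSY_a * w_aj^2 ] / sum_a SSY_a )

with unit-norm component weights ``w_a`` and per-component explained
response sum of squares ``SSY_a``; squared VIPs average to one, and the
conventional selection cutoff is VIP >= 1.0.

Cross-validation supports leave-one-out and Monte-Carlo leave-n-out
schemes. Every fold refits the model — including recomputation of the
autoscaling constants — on the training workers only, so no information
leaks from held-out samples into the predictive statistics. The report
carries accuracy, the mean training R^2(Y) and the predictive Q^2 =
1 - PRESS/TSS with TSS taken about the training-fold means (Q^2 can be
negative; 1 is perfect). Class probabilities are a linear rescaling of
the continuous PLS prediction between the coded class values, clipped to
[0, 1] — a deterministic, monotone mapping.

An unsupervised PCA variance decomposition is provided to check that
group separation exists without supervised selection (an overfitting
control for the PLS-DA).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LEAVE_ONE_OUT = "leave_one_out"
MONTE_CARLO = "monte_carlo_leave_n_out"


@dataclass
class PLSDAModel:
    """Fitted PLS-DA model (single centered {0,1} response)."""

    classes: tuple[str, str]          # classes[0] -> 0, classes[1] -> 1
    feature_names: list[str]          # features kept after variance screen
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    weights: np.ndarray               # (a, p) unit-norm rows
    loadings: np.ndarray              # (a, p)
    scores: np.ndarray                # (n, a)
    y_loadings: np.ndarray            # (a,)
    ssy_explained: np.ndarray         # (a,) explained Y sum of squares
    n_components: int = 0

    def __post_init__(self) -> None:
        self.n_components = self.weights.shape[0]


def _encode(y, classes: tuple[str, str] | None) -> tuple[np.ndarray, tuple[str, str]]:
    labels = np.asarray(y)
    uniq = sorted(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two classes, got {uniq}")
    if classes is None:
        classes = (uniq[0], uniq[1])
    return (labels == classes[1]).astype(float), classes


def fit_plsda(
    X: pd.DataFrame | np.ndarray,
    y,
    n_components: int = 2,
    classes: tuple[str, str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PLSDAModel:
    """Fit PLS-DA by NIPALS with deflation.

    ``X`` is workers x features; features are autoscaled (zero-variance
    features dropped with a warning). With a single response column the
    inner NIPALS loop converges immediately, but the general iteration is
    retained with a ``tol`` convergence check. Components whose scores
    carry (numerically) no variance terminate extraction early.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        names = [f"f{j}" for j in range(Xv.shape[1])]
    y01, classes = _encode(y, classes)
    if len(y01) != Xv.shape[0]:
        raise ValueError("X and y length mismatch")
    if min((y01 == 0).sum(), (y01 == 1).sum()) < 2:
        raise ValueError("need at least two workers per class")

    mean = Xv.mean(axis=0)
    scale = Xv.std(axis=0, ddof=1)
    keep = scale > 0
    if not keep.all():
        warnings.warn(
            f"dropping {(~keep).sum()} zero-variance feature(s)", stacklevel=2
        )
    Xv = (Xv[:, keep] - mean[keep]) / scale[keep]
    names = [n for n, k in zip(names, keep) if k]
    n, p = Xv.shape
    y_mean = float(y01.mean())
    yc = y01 - y_mean

    W, P, T, Q, SSY = [], [], [], [], []
    Xd, yd = Xv.copy(), yc.copy()
    for _ in range(n_components):
        if float(yd @ yd) <= tol or not np.any(np.abs(Xd) > tol):
            break
        u = yd.copy()
        w = np.zeros(p)
        for _ in range(max_iter):
            w_new = Xd.T @ u
            norm = np.linalg.norm(w_new)
            if norm == 0:
                break
            w_new /= norm
            t = Xd @ w_new
            tt = float(t @ t)
            if tt == 0:
                break
            q = float(yd @ t) / tt
            if q == 0:
                break
            u = yd * q / (q * q)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
        t = Xd @ w
        tt = float(t @ t)
        if tt <= tol:
            break
        q = float(yd @ t) / tt
        p_load = Xd.T @ t / tt
        Xd = Xd - np.outer(t, p_load)
        yd = yd - q * t
        W.append(w)
        P.append(p_load)
        T.append(t)
        Q.append(q)
        SSY.append(q * q * tt)

    if not W:
        raise ValueError("no PLS component could be extracted")
    return PLSDAModel(
        classes=classes,
        feature_names=names,
        x_mean=mean[keep],
        x_scale=scale[keep],
        y_mean=y_mean,
        weights=np.array(W),
        loadings=np.array(P),
        scores=np.column_stack(T),
        y_loadings=np.array(Q),
        ssy_explained=np.array(SSY),
    )


def predict_plsda(model: PLSDAModel, X: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Predict held-out workers.

    Returns continuous ``y_pred`` (on the 0/1 coded scale), the assigned
    ``class`` (nearest coded value) and ``prob`` — the probability of
    membership in ``model.classes[1]`` from the clipped linear mapping of
    the prediction onto [0, 1].
    """
    if isinstance(X, pd.DataFrame):
        Xv = X[model.feature_names].to_numpy(dtype=float)
        index = X.index
    else:
        Xv = np.asarray(X, dtype=float)
        index = pd.RangeIndex(Xv.shape[0])
    Xd = (Xv - model.x_mean) / model.x_scale
    yhat = np.full(Xd.shape[0], model.y_mean)
    for a in range(model.n_components):
        t = Xd @ model.weights[a]
        Xd = Xd - np.outer(t, model.loadings[a])
        yhat = yhat + model.y_loadings[a] * t
    prob = np.clip(yhat, 0.0, 1.0)
    assigned = np.where(yhat >= 0.5, model.classes[1], model.classes[0])
    return pd.DataFrame(
        {"y_pred": yhat, "class": assigned, "prob": prob}, index=index
    )


def vip_scores(model: PLSDAModel) -> pd.Series:
    """VIP score per feature; squared scores average to 1."""
    ssy = model.ssy_explained
    total = ssy.sum()
    if total <= 0:
        raise ValueError("model explains no response variance")
    w2 = model.weights**2  # rows already unit-norm
    p = w2.shape[1]
    vip = np.sqrt(p * (ssy @ w2) / total)
    return pd.Series(vip, index=model.feature_names, name="vip")


def select_discriminant(
    vips: pd.Series, cutoff: float = 1.0, top_k: int | None = None
) -> list[str]:
    """Features with VIP >= cutoff, descending; optionally truncated."""
    selected = vips[vips >= cutoff].sort_values(ascending=False, kind="stable")
    names = selected.index.tolist()
    if top_k is not None:
        names = names[:top_k]
    return names


@dataclass
class CVReport:
    """Aggregate cross-validation result."""

    scheme: str
    n_repeats: int
    n_components: int
    accuracy: float
    r2: float
    q2: float
    class_probability: pd.Series = field(repr=False)  # mean P(classes[1]) per subject
    n_evaluations: pd.Series = field(repr=False)
    skipped_folds: int = 0


def _stratified_holdout(
    y01: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    idx0 = np.flatnonzero(y01 == 0)
    idx1 = np.flatnonzero(y01 == 1)
    k0 = max(1, size // 2)
    k1 = max(1, size - k0)
    k0 = min(k0, len(idx0) - 2)  # leave >= 2 per class in training
    k1 = min(k1, len(idx1) - 2)
    if k0 < 1 or k1 < 1:
        raise ValueError("holdout too large for the class sizes")
    pick0 = rng.choice(idx0, size=k0, replace=False)
    pick1 = rng.choice(idx1, size=k1, replace=False)
    return np.sort(np.concatenate([pick0, pick1]))


def cross_validate(
    X: pd.DataFrame,
    y,
    features: list[str] | None = None,
    scheme: str = MONTE_CARLO,
    n_repeats: int = 50,
    holdout_size: int | None = None,
    n_components: int = 2,
    classes: tuple[str, str] | None = None,
    seed: int | np.random.Generator = 0,
) -> CVReport:
    """Cross-validate a PLS-DA model on ``X`` (workers x features).

    Every fold refits on training workers only, with autoscaling
    recomputed inside the fold. ``holdout_size`` (Monte-Carlo scheme)
    defaults to a quarter of the cohort, split evenly between classes.
    """
    if features is not None:
        X = X[features]
    y = pd.Series(np.asarray(y), index=X.index) if not isinstance(y, pd.Series) else y
    y = y.loc[X.index]
    y01, classes = _encode(y.to_numpy(), classes)
    n = len(X)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if scheme == LEAVE_ONE_OUT:
        folds = [np.array([i]) for i in range(n)]
    elif scheme == MONTE_CARLO:
        if holdout_size is None:
            holdout_size = max(2, n // 4)
        folds = [
            _stratified_holdout(y01, holdout_size, rng) for _ in range(n_repeats)
        ]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    press = tss = 0.0
    correct = total = 0
    r2_sum = 0.0
    skipped = 0
    prob_sum = pd.Series(0.0, index=X.index)
    prob_n = pd.Series(0, index=X.index)
    used_folds = 0
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        y_train = y01[train_mask]
        if min((y_train == 0).sum(), (y_train == 1).sum()) < 2:
            skipped += 1
            logger.warning("skipping degenerate fold (a class nearly empty)")
            continue
        try:
            model = fit_plsda(
                X.iloc[train_mask],
                y.iloc[train_mask].to_numpy(),
                n_components=n_components,
                classes=classes,
            )
        except ValueError:
            skipped += 1
            continue
        pred = predict_plsda(model, X.iloc[test_idx])
        y_test = y01[test_idx]
        press += float(((y_test - pred["y_pred"].to_numpy()) ** 2).sum())
        tss += float(((y_test - y_train.mean()) ** 2).sum())
        correct += int((pred["class"].to_numpy() == y.iloc[test_idx].to_numpy()).sum())
        total += len(test_idx)
        ssy_total = float(((y_train - y_train.mean()) ** 2).sum())
        r2_sum += float(model.ssy_explained.sum()) / ssy_total if ssy_total else 0.0
        prob_sum.iloc[test_idx] += pred["prob"].to_numpy()
        prob_n.iloc[test_idx] += 1
        used_folds += 1

    if used_folds == 0:
        raise ValueError("all cross-validation folds were degenerate")
    mean_prob = prob_sum / prob_n.replace(0, np.nan)
    return CVReport(
        scheme=scheme,
        n_repeats=len(folds),
        n_components=n_components,
        accuracy=correct / total,
        r2=r2_sum / used_folds,
        q2=1.0 - press / tss if tss > 0 else float("nan"),
        class_probability=mean_prob,
        n_evaluations=prob_n,
        skipped_folds=skipped,
    )


@dataclass
class PCAResult:
    explained_fraction: np.ndarray  # per-component fractions, sum to 1
    scores: pd.DataFrame            # workers x components


def pca_variance(X: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """Unsupervised centered PCA of workers x features data.

    Fractions are eigenvalue shares of the total variance and sum to one
    over all non-trivial components.
    """
    Xv = X.to_numpy(dtype=float)
    if Xv.shape[0] < 2:
        raise ValueError("need at least two workers")
    Xc = Xv - Xv.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    total = float((s**2).sum())
    if total == 0:
        raise ValueError("constant matrix has no principal components")
    fractions = s**2 / total
    k = n_components or len(s)
    scores = pd.DataFrame(
        u[:, :k] * s[:k],
        index=X.index,
        columns=[f"PC{i + 1}" for i in range(min(k, len(s)))],
    )
    return PCAResult(explained_fraction=fractions[:k], scores=scores)
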