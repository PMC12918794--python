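"""Two-class PLS-DA with conditional down-sampling and signed VIP scoring.

A NIPALS PLS1 core (deterministic, with X and y deflation) is wrapped in the
iteration scheme used for imbalanced dependency profiles: cap the class ratio
by down-sampling the majority class, select the number of latent variables by
stratified cross-validated ROC AUC, compute VIP over the first (up to) two
latent variables and sign it by logistic-regression direction, then aggregate
over iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .errors import DataError
from .io_model import AnalysisConfig, child_seed

logger = logging.getLogger(__name__)


@dataclass
class PlsdaModel:
    feature_names: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    weights: np.ndarray    # p x k, unit-norm columns
    loadings: np.ndarray   # p x k
    q: np.ndarray          # k, y-loadings
    scores: np.ndarray     # n x k, training LV scores
    ssy: np.ndarray        # k, y-variance explained per LV

    @property
    def n_lv(self) -> int:
        return self.weights.shape[1]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Continuous predictions for raw-feature rows (training standardization)."""
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_sd
        yhat = np.full(Xs.shape[0], self.y_mean)
        E = Xs.copy()
        for a in range(self.n_lv):
            t = E @ self.weights[:, a]
            yhat += t * self.q[a]
            E -= np.outer(t, self.loadings[:, a])
        return yhat

    def transform(self, X: np.ndarray) -> np.ndarray:
        """LV scores for raw-feature rows."""
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_sd
        T = np.empty((Xs.shape[0], self.n_lv))
        E = Xs.copy()
        for a in range(self.n_lv):
            t = E @ self.weights[:, a]
            T[:, a] = t
            E -= np.outer(t, self.loadings[:, a])
        return T


@dataclass
class CvResult:
    k_grid: list[int]
    mean_auc: dict[int, float]
    sd_auc: dict[int, float]
    chosen_k: int
    fold_aucs: dict[int, list[float]] = field(default_factory=dict)


def downsample_condition(labels: np.ndarray, ratio_cap: float, seed: int) -> np.ndarray:
    """Indices retained after capping majority/minority at ``ratio_cap``."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2 or counts.min() == 0:
        raise DataError("need two nonempty classes")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_maj / n_min <= ratio_cap:
        return np.arange(labels.size)
    keep_maj = int(np.floor(ratio_cap * n_min))
    maj_idx = np.flatnonzero(labels == majority)
    rng = np.random.default_rng(seed)
    sampled = rng.choice(maj_idx, size=keep_maj, replace=False)
    retained = np.sort(np.concatenate([np.flatnonzero(labels == minority), sampled]))
    return retained


def fit_pls(X: pd.DataFrame | np.ndarray, y: np.ndarray, k: int) -> PlsdaModel:
    """NIPALS PLS1 on standardized X and centered 0/1 y; deterministic."""
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=1)
    if np.any(x_sd == 0):
        raise DataError("zero-variance feature; drop before fitting")
    Xs = (X - x_mean) / x_sd
    y_mean = float(y.mean())
    yr = y - y_mean

    n, p = Xs.shape
    W = np.zeros((p, k))
    P = np.zeros((p, k))
    Q = np.zeros(k)
    T = np.zeros((n, k))
    SSY = np.zeros(k)
    E, f = Xs.copy(), yr.copy()
    n_extracted = 0
    for a in range(k):
        cov = E.T @ f
        norm = np.linalg.norm(cov)
        if norm < 1e-12:
            logger.info("PLS extraction stopped at %d LVs (no residual covariance)", a)
            break
        w = cov / norm
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        p_load = (E.T @ t) / tt
        q = float(f @ t) / tt
        E = E - np.outer(t, p_load)
        f = f - t * q
        W[:, a], P[:, a], Q[a], T[:, a] = w, p_load, q, t
        SSY[a] = q * q * tt
        n_extracted += 1
    if n_extracted == 0:
        raise DataError("could not extract any latent variable")
    sl = slice(0, n_extracted)
    return PlsdaModel(feature_names, x_mean, x_sd, y_mean,
                      W[:, sl], P[:, sl], Q[sl], T[:, sl], SSY[sl])


def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % n_folds].append(j)
    return [np.array(sorted(f)) for f in folds]


def cv_select_k(X: np.ndarray, y: np.ndarray, k_grid: list[int] | None = None,
                folds: int = 5, seed: int = 0) -> CvResult:
    """Stratified CV over the LV grid; smallest k within 1e-12 of the best AUC."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise DataError("each class must have at least `folds` members")
    if k_grid is None:
        k_grid = list(range(1, min(10, X.shape[1], X.shape[0] - 1) + 1))
    rng = np.random.default_rng(seed)
    fold_idx = _stratified_folds(y, folds, rng)
    fold_aucs: dict[int, list[float]] = {k: [] for k in k_grid}
    for test in fold_idx:
        train = np.setdiff1d(np.arange(y.size), test)
        Xtr, Xte = X[train], X[test]
        keep = Xtr.std(axis=0, ddof=1) > 0
        model_max = fit_pls(Xtr[:, keep], y[train].astype(float), max(k_grid))
        for k in k_grid:
            sub = PlsdaModel(model_max.feature_names, model_max.x_mean, model_max.x_sd,
                             model_max.y_mean, model_max.weights[:, :k],
                             model_max.loadings[:, :k], model_max.q[:k],
                             model_max.scores[:, :k], model_max.ssy[:k]) \
                if k <= model_max.n_lv else model_max
            scores = sub.decision_scores(Xte[:, keep])
            fold_aucs[k].append(float(roc_auc_score(y[test], scores)))
    mean_auc = {k: float(np.mean(v)) for k, v in fold_aucs.items()}
    sd_auc = {k: float(np.std(v, ddof=1)) for k, v in fold_aucs.items()}
    best = max(mean_auc.values())
    chosen = min(k for k in k_grid if mean_auc[k] >= best - 1e-12)
    return CvResult(list(k_grid), mean_auc, sd_auc, chosen, fold_aucs)


def vip(model: PlsdaModel, n_lv: int = 2) -> pd.Series:
    """VIP over the first ``n_lv`` latent variables (unsigned).

    VIP_j = sqrt(p * sum_a SSY_a w_ja^2 / sum_a SSY_a) with unit-norm weights,
    so mean(VIP^2) = 1 over features.
    """
    if model.n_lv < n_lv:
        raise ValueError(f"model has only {model.n_lv} LVs")
    W = model.weights[:, :n_lv]
    ssy = model.ssy[:n_lv]
    p = W.shape[0]
    denom = ssy.sum()
    if denom <= 0:
        return pd.Series(np.ones(p), index=model.feature_names, name="VIP")
    contrib = (W**2 * ssy).sum(axis=1) / denom
    return pd.Series(np.sqrt(p * contrib), index=model.feature_names, name="VIP")


def sign_vip(vip_scores: pd.Series, X: np.ndarray, y: np.ndarray,
             C: float = 1.0) -> pd.DataFrame:
    """Sign VIP by the direction of an L2-penalized logistic fit on standardized X.

    Positive sign means association with the class coded 1.
    """
    X = np.asarray(X, dtype=float)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=2000)  # default L2 penalty
    clf.fit(Xs, np.asarray(y).astype(int))
    if clf.n_iter_[0] >= 2000:
        raise DataError("logistic sign fit did not converge")
    sign = np.sign(clf.coef_.ravel())
    sign[sign == 0] = 1.0
    return pd.DataFrame({
        "VIP": vip_scores.to_numpy(),
        "sign": sign,
        "signed_VIP": vip_scores.to_numpy() * sign,
    }, index=vip_scores.index)


def run_iterations(X: pd.DataFrame, y: pd.Series, config: AnalysisConfig,
                   folds: int = 5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full iteration scheme: down-sample, CV-select k, fit, VIP, sign, aggregate.

    ``X``: samples x features; ``y``: 0/1 labels (1 = melanocytic-like).
    Returns (aggregated VIP table, per-iteration CV table).
    """
    y_arr = y.to_numpy() if isinstance(y, pd.Series) else np.asarray(y)
    signed = pd.DataFrame(np.nan, index=X.columns,
                          columns=range(config.n_plsda_iterations))
    cv_rows = []
    for it in range(config.n_plsda_iterations):
        seed_it = child_seed(config.rng_seed, f"plsda_iter_{it}")
        retained = downsample_condition(y_arr, config.class_ratio_cap, seed_it)
        Xr = X.iloc[retained]
        yr = y_arr[retained].astype(int)
        keep = Xr.std(axis=0, ddof=1) > 0
        Xr = Xr.loc[:, keep]
        cv = cv_select_k(Xr.to_numpy(), yr, folds=folds, seed=seed_it)
        model = fit_pls(Xr, yr.astype(float), max(cv.chosen_k, 1))
        n_lv_vip = min(2, model.n_lv)
        v = vip(model, n_lv=n_lv_vip)
        sv = sign_vip(v, Xr.to_numpy(), yr)
        signed.loc[sv.index, it] = sv["signed_VIP"]
        cv_rows.append({
            "iteration": it, "chosen_k": cv.chosen_k,
            "cv_auc": cv.mean_auc[cv.chosen_k],
            "cv_auc_sd": cv.sd_auc[cv.chosen_k],
            "n_retained": len(retained),
        })
    agg = pd.DataFrame({
        "mean_signed_VIP": signed.mean(axis=1),
        "sd_signed_VIP": signed.std(axis=1, ddof=1),
        "n_iterations": signed.notna().sum(axis=1),
    })
    agg["abs_VIP"] = agg["mean_signed_VIP"].abs()
    agg["hit_strict"] = agg["abs_VIP"] >= config.vip_cutoff
    agg["hit_permissive"] = agg["abs_VIP"] >= config.vip_cutoff_permissive
    agg["selection_freq_strict"] = (signed.abs() >= config.vip_cutoff).mean(axis=1)
    cv_table = pd.DataFrame(cv_rows)
    return agg, cv_table
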