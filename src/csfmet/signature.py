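"""Elastic-net signature selection and ROC/AUC validation.

The discriminatory signature is selected on cohort 1 with an elastic-net
regularized logistic regression (mixing 0.5 between L1 and L2), features
standardized to zero mean / unit variance on cohort 1.  The penalty is
chosen by balanced 7-fold cross-validation (five patients from each
phenotype per fold, remainder dealt round-robin) with the one-standard-error
rule on the cross-validated binomial deviance.  The selected model is refit
on all of cohort 1 and validated by predicting cohort 2 (ROC/AUC).

Objective, for mixing ``alpha`` and penalty ``lam``::

    (1/n) * binomial_deviance(beta0, beta)
        + lam * (alpha * ||beta||_1 + (1 - alpha)/2 * ||beta||_2^2)

with an unpenalized intercept.  The lambda grid is log-spaced over
``[lambda_min_ratio * lambda_max, lambda_max]`` where ``lambda_max`` is the
smallest penalty shrinking every coefficient to zero, obtained analytically
from the null-model KKT condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._enet import enet_logistic_path

#: fixed class encoding everywhere downstream
CLASS_CODES = {"RRMS": 0, "PMS": 1}


@dataclass
class EnetPath:
    """Coefficient path and (after CV) the deviance curve and chosen lambdas."""

    lambdas: np.ndarray              # decreasing
    coefs: np.ndarray                # (L, p)
    intercepts: np.ndarray           # (L,)
    feature_ids: list[str]
    alpha_mix: float
    cv_mean_deviance: np.ndarray | None = None
    cv_se: np.ndarray | None = None
    lambda_min: float | None = None
    lambda_1se: float | None = None

    def index_of(self, lam: float) -> int:
        return int(np.argmin(np.abs(self.lambdas - lam)))


@dataclass
class Signature:
    """Selected features ranked by |coefficient|, with the training
    standardization parameters (cohort-1 means/sds) baked in."""

    feature_ids: list[str]
    coefficients: np.ndarray
    intercept: float
    train_mean: pd.Series
    train_sd: pd.Series
    lambda_used: float | None = None

    def __len__(self) -> int:
        return len(self.feature_ids)


def standardize(X: np.ndarray, mean: np.ndarray | None = None,
                sd: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Zero-mean unit-variance scaling; returns (Xs, mean, sd).  When mean/sd
    are supplied (validation cohort), they are applied unchanged."""
    X = np.asarray(X, float)
    if mean is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
    if np.any(sd <= 0):
        raise ValueError("standardization sd must be positive for every feature")
    return (X - mean) / sd, mean, sd


def make_balanced_folds(labels: pd.Series, k: int = 7, per_class: int = 5,
                        seed: int = 0) -> pd.Series:
    """Phenotype-balanced fold assignment (fold index per subject).

    Each fold receives exactly ``per_class`` subjects of each class where the
    class divides evenly; remaining subjects are dealt round-robin so no fold
    gets more than one extra subject per class.  Deterministic given seed.
    """
    labels = pd.Series(labels)
    rng = np.random.default_rng(seed)
    fold = pd.Series(index=labels.index, dtype=int)
    for cls, members in labels.groupby(labels):
        ids = members.index.to_numpy()
        if len(ids) < k:
            raise ValueError(f"class {cls!r} has fewer members ({len(ids)}) than folds ({k})")
        ids = rng.permutation(ids)
        base = per_class * k
        if len(ids) < base:
            base = (len(ids) // k) * k
        for i, sid in enumerate(ids[:base]):
            fold[sid] = i // (base // k)
        for j, sid in enumerate(ids[base:]):  # round-robin remainder
            fold[sid] = j % k
    return fold


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> np.ndarray:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return -2.0 * (y * np.log(p) + (1 - y) * np.log(1 - p))


def lambda_max(X: np.ndarray, y: np.ndarray, alpha_mix: float) -> float:
    """Smallest penalty at which the all-zero coefficient vector is optimal:
    from the KKT condition of the deviance objective at the null model,
    ``lambda_max = 2 * max_j |x_j . (y - ybar)| / (n * alpha)``."""
    if alpha_mix <= 0:
        raise ValueError("lambda_max undefined for pure ridge (alpha_mix = 0)")
    n = len(y)
    resid = y - y.mean()
    return 2.0 * np.max(np.abs(X.T @ resid)) / (n * alpha_mix)


def fit_enet_path(X: np.ndarray, y: np.ndarray, feature_ids=None,
                  alpha_mix: float = 0.5, n_lambda: int = 100,
                  lambda_min_ratio: float = 0.01,
                  lambdas: np.ndarray | None = None) -> EnetPath:
    """Fit the coefficient path over a decreasing lambda grid (warm-started)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required to fit the model")
    n, p = X.shape
    if lambdas is None:
        lmax = lambda_max(X, y, alpha_mix)
        lambdas = np.logspace(np.log10(lmax), np.log10(lambda_min_ratio * lmax), n_lambda)
    lambdas = np.asarray(lambdas, float)

    coefs, intercepts = enet_logistic_path(X, y, lambdas, alpha_mix)
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(p)]
    return EnetPath(lambdas=lambdas, coefs=coefs, intercepts=intercepts,
                    feature_ids=list(feature_ids), alpha_mix=alpha_mix)


def penalized_deviance(X: np.ndarray, y: np.ndarray, beta0: float, beta: np.ndarray,
                       lam: float, alpha_mix: float) -> float:
    """The objective value; used by tests to check the optimizer contract."""
    eta = beta0 + X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    dev = _binomial_deviance(np.asarray(y, float), p).mean()
    pen = lam * (alpha_mix * np.abs(beta).sum() + (1 - alpha_mix) / 2 * (beta ** 2).sum())
    return float(dev + pen)


def cv_select_lambda(X: np.ndarray, y: np.ndarray, folds: pd.Series | np.ndarray,
                     path: EnetPath) -> EnetPath:
    """Cross-validated deviance curve over the path's lambda grid; sets
    ``lambda_min`` (curve minimum) and ``lambda_1se`` (largest lambda whose
    mean deviance is within one standard error of the minimum, SE taken at
    the minimum: sd of fold means / sqrt(k))."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    folds = np.asarray(folds)
    fold_ids = np.unique(folds)
    fold_dev = np.zeros((len(fold_ids), len(path.lambdas)))
    for fi, f in enumerate(fold_ids):
        tr, te = folds != f, folds == f
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {f} does not contain both classes")
        sub = fit_enet_path(X[tr], y[tr], feature_ids=path.feature_ids,
                            alpha_mix=path.alpha_mix, lambdas=path.lambdas)
        eta = sub.intercepts[:, None] + sub.coefs @ X[te].T  # (L, n_te)
        p = 1.0 / (1.0 + np.exp(-eta))
        fold_dev[fi] = _binomial_deviance(y[te][None, :], p).mean(axis=1)
    mean_dev = fold_dev.mean(axis=0)
    se = fold_dev.std(axis=0, ddof=1) / np.sqrt(len(fold_ids))
    i_min = int(np.argmin(mean_dev))
    thresh = mean_dev[i_min] + se[i_min]
    # lambdas are decreasing: the largest qualifying lambda is the first index
    i_1se = int(np.flatnonzero(mean_dev <= thresh)[0])
    path.cv_mean_deviance = mean_dev
    path.cv_se = se
    path.lambda_min = float(path.lambdas[i_min])
    path.lambda_1se = float(path.lambdas[i_1se])
    return path


def extract_signature(path: EnetPath, at: float | None = None,
                      train_mean: pd.Series | None = None,
                      train_sd: pd.Series | None = None) -> Signature:
    """Nonzero-coefficient features at the given lambda (default lambda_1se),
    ranked by |coefficient| descending (ties broken by feature id)."""
    lam = path.lambda_1se if at is None else at
    if lam is None:
        raise ValueError("run cv_select_lambda first or pass an explicit lambda")
    i = path.index_of(lam)
    beta = path.coefs[i]
    nz = np.flatnonzero(beta != 0)
    if len(nz) == 0:
        warnings.warn("empty signature: all coefficients are zero at this lambda")
    order = sorted(nz, key=lambda j: (-abs(beta[j]), path.feature_ids[j]))
    ids = [path.feature_ids[j] for j in order]
    p = len(path.feature_ids)
    if train_mean is None:
        train_mean = pd.Series(np.zeros(p), index=path.feature_ids)
    if train_sd is None:
        train_sd = pd.Series(np.ones(p), index=path.feature_ids)
    return Signature(feature_ids=ids, coefficients=beta[order],
                     intercept=float(path.intercepts[i]),
                     train_mean=train_mean.loc[ids] if ids else train_mean.iloc[:0],
                     train_sd=train_sd.loc[ids] if ids else train_sd.iloc[:0],
                     lambda_used=float(lam))


def predict_scores(sig: Signature, X_new: pd.DataFrame) -> np.ndarray:
    """Logistic score 1/(1+exp(-(b0 + x.beta))) on new samples.

    ``X_new`` is samples x features on the *unstandardized* harmonized scale;
    the signature's cohort-1 standardization parameters are applied.
    """
    missing = [f for f in sig.feature_ids if f not in X_new.columns]
    if missing:
        raise KeyError(f"unknown feature id(s): {missing}")
    if len(sig) == 0:
        return np.full(len(X_new), 1.0 / (1.0 + np.exp(-sig.intercept)))
    Xs = (X_new[sig.feature_ids].to_numpy(float) - sig.train_mean.to_numpy()) / sig.train_sd.to_numpy()
    eta = sig.intercept + Xs @ sig.coefficients
    return 1.0 / (1.0 + np.exp(-eta))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected Mann-Whitney AUC:
    (#{pos > neg} + 0.5 * #{pos = neg}) / (n_pos * n_neg)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required for AUC")
    ranks = rankdata(scores)  # average ranks handle ties
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))


def per_feature_auc(X: pd.DataFrame, labels: np.ndarray) -> pd.Series:
    """AUC of each feature column used directly as a score (no sign flipping:
    anti-correlated features report AUC < 0.5)."""
    return pd.Series({c: roc_auc(X[c].to_numpy(float), labels) for c in X.columns},
                     name="auc")


def select_signature(X: pd.DataFrame, labels: pd.Series, alpha_mix: float = 0.5,
                     k_folds: int = 7, per_class: int = 5, n_lambda: int = 100,
                     lambda_min_ratio: float = 0.01, seed: int = 0
                     ) -> tuple[Signature, EnetPath]:
    """End-to-end selection on a training cohort: standardize, CV the path
    with balanced folds, pick lambda_1se, refit on all training subjects."""
    y = labels.map(CLASS_CODES).to_numpy(float)
    Xs, mean, sd = standardize(X.to_numpy(float))
    folds = make_balanced_folds(labels, k=k_folds, per_class=per_class, seed=seed)
    path = fit_enet_path(Xs, y, feature_ids=list(X.columns), alpha_mix=alpha_mix,
                         n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio)
    path = cv_select_lambda(Xs, y, folds.loc[labels.index].to_numpy(), path)
    sig = extract_signature(path,
                            train_mean=pd.Series(mean, index=X.columns),
                            train_sd=pd.Series(sd, index=X.columns))
    return sig, path
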