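"""Transductive Mondrian (class-conditional) conformal classification.

For each test sample and each hypothesized phenotype, the underlying
probability-calibrated support-vector classifier is retrained on the
training set augmented with the test sample under that label.  The margin
nonconformity score of every example is computed under its own label, and
the Mondrian p-value ranks the test sample's score only among examples of
the hypothesized class (counting the test sample itself, so p >= 1/(n+1)):

    p(y_hat) = #{ j : y_j = y_hat, alpha_j >= alpha_x } / (n_yhat + 1)

A high p-value means high similarity to that phenotype.  Prediction sets at
significance epsilon contain the labels with p > epsilon, giving empty,
single or double predictions; validity guarantees the true label is
excluded in at most a fraction epsilon of predictions (per class, by the
Mondrian construction).  Smoothed p-values (ties weighted by a seeded
uniform draw) are available for exact-uniformity diagnostics.

Class encoding is fixed: RRMS = 0, PMS = 1.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import LeaveOneOut
from sklearn.svm import SVC

from .signature import CLASS_CODES


def _fit_quiet(clf, X, y):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        clf.fit(X, y)
    return clf


CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}
KERNELS = ("linear", "rbf", "sigmoid", "polynomial")


@dataclass
class ClassifierSpec:
    """Support-vector classifier settings with internal cross-validated
    sigmoid probability calibration (seeded)."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | None = None   # None -> 1/(p * Var(X)) ("scale")
    degree: int = 3              # polynomial only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.C <= 0:
            raise ValueError("cost C must be positive")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")

    def build(self, probability: bool = True) -> SVC:
        return SVC(kernel="poly" if self.kernel == "polynomial" else self.kernel,
                   C=self.C, gamma=self.gamma if self.gamma is not None else "scale",
                   degree=self.degree, probability=probability,
                   random_state=self.seed)


@dataclass
class ConformalPValues:
    """Per evaluated sample, one conformal p-value per phenotype class."""

    p: pd.DataFrame            # columns RRMS, PMS; index = sample ids
    p_smoothed: pd.DataFrame | None = None
    smoothing: bool = False

    def frame(self) -> pd.DataFrame:
        return self.p_smoothed if self.smoothing else self.p


@dataclass
class PredictionSet:
    epsilon: float
    labels: frozenset
    kind: str  # empty | single | double


@dataclass
class CurveSet:
    """Prediction-set composition (and, when truth is known, error rates)
    along an epsilon grid."""

    epsilon: np.ndarray
    frac_empty: np.ndarray
    frac_single: np.ndarray
    frac_double: np.ndarray
    error_rate: np.ndarray | None = None
    error_rate_by_class: pd.DataFrame | None = None

    @property
    def peak_single_epsilon(self) -> float:
        """Smallest epsilon attaining the maximum single-label fraction."""
        return float(self.epsilon[int(np.argmax(self.frac_single))])

    def frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"epsilon": self.epsilon, "frac_empty": self.frac_empty,
                            "frac_single": self.frac_single, "frac_double": self.frac_double})
        if self.error_rate is not None:
            out["error_rate"] = self.error_rate
        return out


def margin_nonconformity(prob: dict | np.ndarray, y) -> float:
    """Margin nonconformity: 0.5 - (P(y) - max_{y' != y} P(y'))/2.

    For two classes this reduces to 1 - P(y).  ``prob`` maps class -> P or is
    an array indexed by class code; probabilities must sum to 1.
    """
    if isinstance(prob, dict):
        probs = np.array([prob[k] for k in sorted(prob)])
        y_idx = sorted(prob).index(y)
    else:
        probs = np.asarray(prob, float)
        y_idx = int(y)
    if abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError("class probabilities must sum to 1")
    others = np.delete(probs, y_idx)
    return float(0.5 - (probs[y_idx] - others.max()) / 2.0)


def _margin_scores(probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized binary margin nonconformity under each example's own label:
    alpha = 0.5 - (P(y) - P(other))/2 = 1 - P(y)."""
    own = probs[np.arange(len(labels)), labels.astype(int)]
    return 1.0 - own


def mondrian_pvalue(class_alphas: np.ndarray, alpha_x: float,
                    tau: float | None = None) -> float:
    """Rank-based Mondrian p-value given the nonconformity scores of every
    class member *including the test sample itself*.

    Deterministic (non-strict tie count) when ``tau`` is None, else smoothed
    with the supplied U(0,1) draw.  Invariant to any strictly increasing
    transform of the scores.
    """
    class_alphas = np.asarray(class_alphas, float)
    n = len(class_alphas)
    if tau is None:
        return float(np.sum(class_alphas >= alpha_x) / n)
    n_gt = int(np.sum(class_alphas > alpha_x))
    n_eq = int(np.sum(class_alphas == alpha_x))
    return float((n_gt + tau * n_eq) / n)


def tcp_pvalues(train_X: np.ndarray, train_y: np.ndarray, test_X: np.ndarray,
                spec: ClassifierSpec, smoothing: bool = False, seed: int = 0,
                sample_ids=None) -> ConformalPValues:
    """Transductive Mondrian p-values for every test sample and both classes.

    One classifier refit per (test sample, hypothesized label).  Both the
    deterministic (non-strict tie count) and the smoothed p-values are
    computed from the same fits; ``smoothing`` selects which one
    :meth:`ConformalPValues.frame` reports.
    """
    train_X = np.asarray(train_X, float)
    train_y = np.asarray(train_y, int)
    test_X = np.atleast_2d(np.asarray(test_X, float))
    classes = np.unique(train_y)
    if set(classes) != {0, 1}:
        raise ValueError("training set must contain both classes (codes 0 and 1)")
    rng = np.random.default_rng(seed)
    n_test = len(test_X)
    p_det = np.zeros((n_test, 2))
    p_smo = np.zeros((n_test, 2))
    for i in range(n_test):
        for yhat in (0, 1):
            X_aug = np.vstack([train_X, test_X[i]])
            y_aug = np.append(train_y, yhat)
            clf = _fit_quiet(spec.build(probability=True), X_aug, y_aug)
            probs = clf.predict_proba(X_aug)
            # sklearn orders columns by sorted class labels -> 0, 1
            alpha = _margin_scores(probs, y_aug)
            cls_alpha = alpha[y_aug == yhat]     # includes the test sample
            a_x = alpha[-1]
            p_det[i, yhat] = mondrian_pvalue(cls_alpha, a_x)
            p_smo[i, yhat] = mondrian_pvalue(cls_alpha, a_x, tau=rng.uniform())
    cols = [CLASS_NAMES[0], CLASS_NAMES[1]]
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_test)]
    return ConformalPValues(
        p=pd.DataFrame(p_det, index=sample_ids, columns=cols),
        p_smoothed=pd.DataFrame(p_smo, index=sample_ids, columns=cols),
        smoothing=smoothing)


def prediction_sets(pvals: ConformalPValues, epsilon: float) -> list[PredictionSet]:
    """Labels with p > epsilon, per sample."""
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie in (0, 1)")
    out = []
    for _, row in pvals.frame().iterrows():
        labels = frozenset(c for c in row.index if row[c] > epsilon)
        kind = {0: "empty", 1: "single", 2: "double"}[len(labels)]
        out.append(PredictionSet(epsilon=epsilon, labels=labels, kind=kind))
    return out


def efficiency_curve(pvals: ConformalPValues, epsilon_grid: np.ndarray) -> CurveSet:
    """Fractions of empty/single/double prediction sets along the grid."""
    P = pvals.frame().to_numpy(float)
    if len(P) == 0:
        raise ValueError("need at least one sample")
    eps = np.asarray(epsilon_grid, float)
    n_in = (P[None, :, :] > eps[:, None, None]).sum(axis=2)  # (E, n)
    frac_empty = (n_in == 0).mean(axis=1)
    frac_single = (n_in == 1).mean(axis=1)
    frac_double = (n_in == 2).mean(axis=1)
    return CurveSet(eps, frac_empty, frac_single, frac_double)


def calibration_curve(pvals: ConformalPValues, true_labels, epsilon_grid: np.ndarray) -> CurveSet:
    """Observed error rate (true-label p <= epsilon) along the grid, overall
    and per true class (the Mondrian guarantee is per class)."""
    P = pvals.frame()
    true_labels = pd.Series(true_labels, index=P.index)
    names = true_labels.map(CLASS_NAMES) if true_labels.dtype.kind in "iuf" else true_labels
    p_true = np.array([P.loc[i, names[i]] for i in P.index])
    eps = np.asarray(epsilon_grid, float)
    err = (p_true[None, :] <= eps[:, None]).mean(axis=1)
    by_class = {}
    for cls in sorted(names.unique()):
        mask = (names == cls).to_numpy()
        by_class[cls] = (p_true[None, mask] <= eps[:, None]).mean(axis=1)
    eff = efficiency_curve(pvals, eps)
    eff.error_rate = err
    eff.error_rate_by_class = pd.DataFrame(by_class, index=eps)
    return eff


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------

def _loocv_accuracy(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec) -> float:
    correct = 0
    for tr, te in LeaveOneOut().split(X):
        if len(np.unique(y[tr])) < 2:
            continue
        clf = _fit_quiet(spec.build(probability=False), X[tr], y[tr])
        correct += int(clf.predict(X[te])[0] == y[te][0])
    return correct / len(y)


def _stage1_candidates(seed: int) -> list[ClassifierSpec]:
    cands = []
    for c in 2.0 ** np.arange(-3, 4):
        cands.append(ClassifierSpec("linear", C=float(c), seed=seed))
    for kernel in ("rbf", "sigmoid"):
        for c in 2.0 ** np.arange(-3, 4, 2):
            for g in 2.0 ** np.arange(-7, 2, 2):
                cands.append(ClassifierSpec(kernel, C=float(c), gamma=float(g), seed=seed))
    for deg in (2, 3):
        cands.append(ClassifierSpec("polynomial", C=1.0, degree=deg, seed=seed))
    return cands


def grid_search_hyperparams(X: np.ndarray, y: np.ndarray,
                            n_cost: int = 30, n_gamma: int = 30,
                            cost_log2: tuple[float, float] = (-5.0, 15.0),
                            gamma_log2: tuple[float, float] = (-15.0, 3.0),
                            seed: int = 0) -> ClassifierSpec:
    """Two-stage search by leave-one-out accuracy.

    Stage 1 screens a small preset per kernel and picks the best kernel;
    stage 2 refines that kernel on an ``n_cost x n_gamma`` log-spaced (C,
    gamma) grid.  Ties break toward smaller C, then smaller gamma.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if min(np.bincount(y)) < 2:
        raise ValueError("need at least two members per class")

    def best(cands):
        scored = []
        for spec in cands:
            acc = _loocv_accuracy(X, y, spec)
            scored.append((-acc, spec.C, spec.gamma if spec.gamma is not None else 0.0, spec))
        scored.sort(key=lambda t: t[:3])
        return scored[0][3], -scored[0][0]

    spec1, _ = best(_stage1_candidates(seed))
    costs = np.logspace(cost_log2[0], cost_log2[1], n_cost, base=2.0)
    gammas = np.logspace(gamma_log2[0], gamma_log2[1], n_gamma, base=2.0)
    if spec1.kernel == "linear":
        cands = [ClassifierSpec("linear", C=float(c), seed=seed) for c in costs]
    elif spec1.kernel == "polynomial":
        cands = [ClassifierSpec("polynomial", C=float(c), gamma=float(g),
                                degree=spec1.degree, seed=seed)
                 for c, g in itertools.product(costs, gammas)]
    else:
        cands = [ClassifierSpec(spec1.kernel, C=float(c), gamma=float(g), seed=seed)
                 for c, g in itertools.product(costs, gammas)]
    spec2, _ = best(cands)
    return spec2


# ---------------------------------------------------------------------------
# leave-patient-out longitudinal monitoring
# ---------------------------------------------------------------------------

def loo_patient_monitor(baseline_X: pd.DataFrame, baseline_y: pd.Series,
                        baseline_subjects: pd.Series, patient_samples: pd.DataFrame,
                        patient_id: str, spec: ClassifierSpec, smoothing: bool = False,
                        seed: int = 0) -> ConformalPValues:
    """Conformal p-values for one treated patient's samples (baseline and
    follow-ups), trained on all baseline RRMS+PMS samples excluding every
    sample of the evaluated patient."""
    if patient_id not in set(baseline_subjects):
        raise ValueError(f"patient {patient_id} absent from the baseline set")
    keep = (baseline_subjects != patient_id).to_numpy()
    train_X = baseline_X.to_numpy(float)[keep]
    train_y = baseline_y.to_numpy()[keep]
    assert patient_id not in set(baseline_subjects[keep])  # id audit
    return tcp_pvalues(train_X, train_y, patient_samples.to_numpy(float), spec,
                       smoothing=smoothing, seed=seed,
                       sample_ids=list(patient_samples.index))
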