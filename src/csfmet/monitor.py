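"""Signature characterization and longitudinal monitoring statistics.

Covers the downstream analyses run on the selected features: PCA of the
training cohort with projection of new samples (validation cohort,
transitioning patients, treated-patient follow-ups), ANOSIM permutation
tests of group separation, paired Wilcoxon tests of follow-up movement
along PC1, sex-adjusted log2 fold changes, a Mann-Whitney treatment check,
multilevel (random-intercept) clinical-association models with signed
-log10 p "strength" scores, and Spearman-distance hierarchical clustering
of the association profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist, squareform
import statsmodels.api as sm
import statsmodels.formula.api as smf


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaModel:
    center: np.ndarray
    loadings: np.ndarray            # (p, k), orthonormal columns
    explained_variance_ratio: np.ndarray
    scores: np.ndarray              # training scores (n, k)


def pca_fit(X: np.ndarray, n_components: int = 2) -> PcaModel:
    """SVD-based PCA of the column-centered matrix.  Component signs are
    fixed so the largest-|loading| entry of each component is positive."""
    X = np.asarray(X, float)
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if len(s) else 0
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")
    V = Vt[:n_components].T
    flip = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(n_components)])
    V = V * flip
    scores = Xc @ V
    var = s ** 2 / max(len(X) - 1, 1)
    evr = var[:n_components] / var.sum()
    return PcaModel(center=center, loadings=V, explained_variance_ratio=evr, scores=scores)


def pca_project(model: PcaModel, X_new: np.ndarray) -> np.ndarray:
    X_new = np.atleast_2d(np.asarray(X_new, float))
    if X_new.shape[1] != model.loadings.shape[0]:
        raise ValueError("feature dimension mismatch with the fitted model")
    return (X_new - model.center) @ model.loadings


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

@dataclass
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int
    seed: int


def _anosim_r(ranks_condensed: np.ndarray, within_mask: np.ndarray, n: int) -> float:
    r_within = ranks_condensed[within_mask].mean()
    r_between = ranks_condensed[~within_mask].mean()
    return float((r_between - r_within) / (n * (n - 1) / 4.0))


def anosim(X: np.ndarray, groups, n_perm: int = 999, seed: int = 0,
           distances: np.ndarray | None = None) -> AnosimResult:
    """Analysis of similarities on Euclidean dissimilarities (or a supplied
    square distance matrix).

    R contrasts mean between- vs within-group dissimilarity ranks (average
    ranking of ties), scaled to [-1, 1]; the p-value permutes group labels
    with the (hits + 1)/(n_perm + 1) convention.
    """
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    if np.min(np.bincount(pd.factorize(groups)[0])) < 2:
        raise ValueError("every group needs at least two members")
    if distances is None:
        d = pdist(np.asarray(X, float))
    else:
        d = squareform(np.asarray(distances, float), checks=False)
    n = len(groups)
    ranks = stats.rankdata(d)
    iu = np.triu_indices(n, k=1)
    within = groups[iu[0]] == groups[iu[1]]
    r_obs = _anosim_r(ranks, within, n)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        w = perm[iu[0]] == perm[iu[1]]
        if _anosim_r(ranks, w, n) >= r_obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return AnosimResult(R=r_obs, p_value=float(p), n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def paired_wilcoxon(x, y) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired vectors.

    Zero differences are dropped.  The null distribution is exact for small
    n — by exhaustive sign-flip enumeration up to n = 12 (which handles tied
    |differences| exactly), via the closed-form exact distribution for
    n <= 25 without ties — and a tie-corrected normal approximation beyond.
    All differences zero degenerates to p = 1 (with a warning).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero")
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    if n <= 12:
        # exhaustive enumeration of all 2^n sign assignments; the null is
        # symmetric around mu, so the two-sided p is the |W - mu| tail
        W_obs = ranks[d > 0].sum()
        mu = ranks.sum() / 2.0
        signs = np.array(np.meshgrid(*[[0.0, 1.0]] * n)).reshape(n, -1)
        W_all = ranks @ signs
        return float(np.mean(np.abs(W_all - mu) >= abs(W_obs - mu) - 1e-12))
    ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= 25 and not ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method,
                         correction=False, zero_method="wilcox")
    return float(res.pvalue)


def treatment_check(levels, treated_flag) -> float:
    """Two-sided Mann-Whitney p comparing levels in treated vs untreated
    patients (exact for small samples without ties)."""
    levels = np.asarray(levels, float)
    flag = np.asarray(treated_flag, bool)
    a, b = levels[flag], levels[~flag]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both treated and untreated groups must be nonempty")
    method = "exact" if (max(len(a), len(b)) <= 8 and
                         len(np.unique(levels)) == len(levels)) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# adjusted fold changes and clinical associations
# ---------------------------------------------------------------------------

def adjusted_log2fc(levels, group, sex) -> tuple[float, float, float]:
    """Sex-adjusted log2 fold change PMS - RRMS.

    Least squares ``level ~ I(PMS) + I(male)``; the group coefficient equals
    the marginal-means contrast for a two-level factor.  Returns (estimate,
    p, sex_p) with t-statistic p-values.
    """
    df = pd.DataFrame({"level": np.asarray(levels, float),
                       "pms": (np.asarray(group) == "PMS").astype(float),
                       "male": (np.asarray(sex) == "M").astype(float)})
    if df["pms"].nunique() < 2:
        raise ValueError("both phenotype groups required")
    Xd = sm.add_constant(df[["pms", "male"]])
    if np.linalg.matrix_rank(Xd.to_numpy()) < Xd.shape[1]:
        raise ValueError("confounded design: sex and group are not separable")
    fit = sm.OLS(df["level"], Xd).fit()
    return float(fit.params["pms"]), float(fit.pvalues["pms"]), float(fit.pvalues["male"])


@dataclass
class AssociationResult:
    metabolite: str
    measure: str
    estimate: float
    p_value: float
    converged: bool

    @property
    def strength(self) -> float:
        """sign(coefficient) x -log10(p)."""
        return float(np.sign(self.estimate) * -np.log10(self.p_value))


def clinical_association(levels, clinical, time_months, sex, patient_id,
                         metabolite: str = "", measure: str = "") -> AssociationResult:
    """Random-intercept multilevel model of one metabolite against one
    clinical measure across visits::

        level ~ clinical + time + sex + time:clinical + (1 | patient)

    fitted by maximum likelihood; the clinical main-effect estimate is
    reported with a residual-df t-statistic p-value.
    """
    df = pd.DataFrame({"level": np.asarray(levels, float),
                       "clinical": np.asarray(clinical, float),
                       "time": np.asarray(time_months, float),
                       "male": (np.asarray(sex) == "M").astype(float),
                       "patient": np.asarray(patient_id)})
    df = df.dropna()
    counts = df.groupby("patient").size()
    df = df[df["patient"].isin(counts.index[counts >= 2])]
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("level ~ clinical + time + male + time:clinical",
                                df, groups=df["patient"])
            fit = model.fit(reml=False)
        est = float(fit.params["clinical"])
        se = float(fit.bse["clinical"])
        n_fixed = len(fit.fe_params)
        df_resid = max(len(df) - n_fixed - 1, 1)
        p = float(2 * stats.t.sf(abs(est / se), df_resid))
        converged = bool(fit.converged) and np.isfinite(p)
    except Exception:
        est, p, converged = np.nan, np.nan, False
    if not converged:
        return AssociationResult(metabolite, measure, np.nan, np.nan, False)
    return AssociationResult(metabolite, measure, est, p, True)


def association_strengths(results: list[AssociationResult]) -> pd.DataFrame:
    """Metabolite x measure matrix of signed -log10 p strengths; rows with a
    non-converged fit carry NaN (excluded from clustering)."""
    rows = {}
    for r in results:
        rows.setdefault(r.metabolite, {})[r.measure] = r.strength if r.converged else np.nan
    return pd.DataFrame(rows).T.sort_index()


def spearman_hclust(strength: pd.DataFrame) -> list[str]:
    """Average-linkage hierarchical clustering with distance 1 - Spearman rho
    between rows; returns the deterministic leaf order (constant rows have no
    defined correlation and are placed last, in label order)."""
    if len(strength) < 2:
        raise ValueError("need at least two rows to cluster")
    strength = strength.sort_index()  # deterministic tie-break by row label
    usable = strength.index[strength.std(axis=1) > 0]
    flagged = [i for i in strength.index if i not in set(usable)]
    sub = strength.loc[usable]
    if len(sub) < 2:
        return list(usable) + flagged
    rho = stats.spearmanr(sub.to_numpy(float), axis=1)[0]
    if np.ndim(rho) == 0:  # spearmanr collapses the 2-row case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    Z = average(squareform(dist, checks=False))
    order = [sub.index[i] for i in leaves_list(Z)]
    return order + flagged
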