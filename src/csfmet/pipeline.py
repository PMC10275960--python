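"""End-to-end stage drivers over the library modules.

Each stage reads/writes the TSV interchange formats, so the CLI, the
numbered analysis scripts and the acceptance script all run the same code.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import conformal as cp
from . import harmonize as hz
from . import monitor as mo
from . import preprocess as pp
from . import signature as sg
from .config import PipelineConfig
from .io import FeatureTable, InjectionMeta

# ---------------------------------------------------------------------------
# preprocessing + harmonization
# ---------------------------------------------------------------------------

def run_preprocess(table: FeatureTable, meta: InjectionMeta, cfg: PipelineConfig
                   ) -> tuple[FeatureTable, pd.DataFrame]:
    out, reports = pp.preprocess_cohort(
        table, meta, blank_ratio_min=cfg.blank_ratio_min,
        dilution_p_max=cfg.dilution_p_max, loess_span=cfg.loess_span,
        cv_max=cfg.cv_max, tic_mad_factor=cfg.tic_mad_factor)
    return out, pp.report_frame(reports)


def run_harmonize(t1: FeatureTable, t2: FeatureTable, meta: InjectionMeta,
                  cfg: PipelineConfig) -> hz.HarmonizedMatrix:
    return hz.harmonize(t1, t2, meta, ppm_max=cfg.ppm_max, rt_max_s=cfg.rt_max_s,
                        age_p_max=cfg.age_p_max, presence_min=cfg.presence_min)


# ---------------------------------------------------------------------------
# signature selection + validation
# ---------------------------------------------------------------------------

def training_frame(hm: hz.HarmonizedMatrix, cohort: int = 1
                   ) -> tuple[pd.DataFrame, pd.Series]:
    """Patients-by-features frame and phenotype labels for RRMS+PMS study
    samples of one cohort (baseline visit only for treated patients)."""
    meta = hm.sample_meta
    mask = (meta["cohort"] == cohort) & meta["group"].isin(["RRMS", "PMS"])
    baseline = meta["timepoint_months"].isna() | (meta["timepoint_months"] == 0)
    ids = meta.index[mask & baseline]
    X = hm.values[ids].T
    y = meta.loc[ids, "group"]
    return X, y


def run_select(hm: hz.HarmonizedMatrix, cfg: PipelineConfig
               ) -> tuple[sg.Signature, sg.EnetPath, dict]:
    """Select the signature on cohort 1 and validate on cohort 2 (AUC)."""
    X1, y1 = training_frame(hm, cohort=1)
    sig, path = sg.select_signature(
        X1, y1, alpha_mix=cfg.alpha_mix, k_folds=cfg.k_folds,
        per_class=cfg.per_class_fold_size, n_lambda=cfg.n_lambda,
        lambda_min_ratio=cfg.lambda_min_ratio, seed=cfg.seed)
    X2, y2 = training_frame(hm, cohort=2)
    labels2 = y2.map(sg.CLASS_CODES).to_numpy()
    metrics: dict = {"n_selected": len(sig), "lambda_1se": path.lambda_1se,
                     "lambda_min": path.lambda_min}
    if len(sig) > 0:
        scores = sg.predict_scores(sig, X2)
        metrics["auc_cohort2"] = sg.roc_auc(scores, labels2)
        per_feat = sg.per_feature_auc(X2[sig.feature_ids], labels2)
        metrics["best_single_feature_auc"] = float(per_feat.max())
    return sig, path, metrics


# ---------------------------------------------------------------------------
# conformal prediction
# ---------------------------------------------------------------------------

def signature_matrix(hm: hz.HarmonizedMatrix, sig: sg.Signature, ids) -> np.ndarray:
    """Selected-feature submatrix for the given samples, standardized with
    the signature's cohort-1 parameters."""
    X = hm.values.loc[sig.feature_ids, ids].T.to_numpy(float)
    return (X - sig.train_mean.to_numpy()) / sig.train_sd.to_numpy()


def run_conformal(hm: hz.HarmonizedMatrix, sig: sg.Signature, cfg: PipelineConfig,
                  spec: cp.ClassifierSpec | None = None, grid_search: bool = False
                  ) -> dict:
    """Train TCP on cohort 1 and evaluate cohort 2: p-values, efficiency and
    calibration curves, chosen classifier spec."""
    X1, y1 = training_frame(hm, cohort=1)
    X2, y2 = training_frame(hm, cohort=2)
    Xtr = signature_matrix(hm, sig, X1.index)
    Xte = signature_matrix(hm, sig, X2.index)
    ytr = y1.map(sg.CLASS_CODES).to_numpy(int)
    yte = y2.map(sg.CLASS_CODES).to_numpy(int)
    if spec is None:
        if grid_search:
            spec = cp.grid_search_hyperparams(
                Xtr, ytr, n_cost=cfg.n_cost, n_gamma=cfg.n_gamma,
                cost_log2=(cfg.cost_log2_min, cfg.cost_log2_max),
                gamma_log2=(cfg.gamma_log2_min, cfg.gamma_log2_max), seed=cfg.seed)
        else:
            spec = cp.ClassifierSpec("rbf", C=1.0, seed=cfg.seed)
    pv = cp.tcp_pvalues(Xtr, ytr, Xte, spec, smoothing=cfg.smoothing,
                        seed=cfg.seed, sample_ids=list(X2.index))
    grid = cfg.epsilon_grid()
    curves = cp.calibration_curve(pv, pd.Series(yte, index=pv.p.index), grid)
    return {"spec": spec, "pvalues": pv, "curves": curves, "true_labels": yte,
            "peak_single_epsilon": curves.peak_single_epsilon}


def prepare_followups(hm: hz.HarmonizedMatrix, fu: FeatureTable) -> pd.DataFrame:
    """Follow-up samples on the cohort-1 centered scale: log2 values of the
    harmonized features minus the cohort-1 pre-centering feature means.
    Returns features (canonical ids) x follow-up samples."""
    if fu.scale != "log2":
        raise ValueError("follow-up table must be log2-scaled")
    if hm.cohort_means is None:
        raise ValueError("harmonized matrix lacks cohort means")
    ids = list(hm.values.index)
    vals = fu.values.loc[ids].astype(float)
    return vals.sub(hm.cohort_means.loc[ids, "c1"], axis=0)


def run_monitor_conformal(hm: hz.HarmonizedMatrix, sig: sg.Signature,
                          followups: FeatureTable, fu_meta: InjectionMeta,
                          cfg: PipelineConfig, spec: cp.ClassifierSpec | None = None
                          ) -> pd.DataFrame:
    """Leave-patient-out joint-cohort conformal monitoring of treated
    patients across timepoints.  Returns a long frame of p-values."""
    meta = hm.sample_meta
    mask = meta["group"].isin(["RRMS", "PMS"]) & (
        meta["timepoint_months"].isna() | (meta["timepoint_months"] == 0))
    base_ids = meta.index[mask]
    Xb = signature_matrix(hm, sig, base_ids)
    Xb_df = pd.DataFrame(Xb, index=base_ids)
    yb = meta.loc[base_ids, "group"].map(sg.CLASS_CODES).astype(int)
    subj = meta.loc[base_ids, "subject_id"]
    if spec is None:
        spec = cp.ClassifierSpec("rbf", C=1.0, seed=cfg.seed)

    # follow-up samples on the signature features, cohort-1 standardization
    fu_vals = prepare_followups(hm, followups).loc[sig.feature_ids].T
    fu_std = (fu_vals.to_numpy(float) - sig.train_mean.to_numpy()) / sig.train_sd.to_numpy()
    fu_std = pd.DataFrame(fu_std, index=fu_vals.index)

    treated = fu_meta.df[fu_meta.df["treated"]]
    rows = []
    for pid in sorted(treated["subject_id"].unique()):
        own_base = meta.index[(meta["subject_id"] == pid) & mask]
        own_fu = treated.index[treated["subject_id"] == pid]
        samples = pd.concat([Xb_df.loc[own_base], fu_std.loc[own_fu]])
        tps = pd.concat([meta.loc[own_base, "timepoint_months"].fillna(0.0),
                         fu_meta.df.loc[own_fu, "timepoint_months"]])
        pv = cp.loo_patient_monitor(Xb_df, yb, subj, samples, pid, spec,
                                    smoothing=cfg.smoothing, seed=cfg.seed)
        for sid in pv.p.index:
            rows.append(dict(subject_id=pid, sample_id=sid,
                             timepoint_months=float(tps[sid]),
                             p_RRMS=float(pv.frame().loc[sid, "RRMS"]),
                             p_PMS=float(pv.frame().loc[sid, "PMS"])))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# characterization / monitoring statistics
# ---------------------------------------------------------------------------

def run_characterize(hm: hz.HarmonizedMatrix, sig: sg.Signature, cfg: PipelineConfig,
                     followups: FeatureTable | None = None,
                     fu_meta: InjectionMeta | None = None) -> dict:
    """PCA + ANOSIM per cohort on the selected features; if follow-ups are
    given, project them and run paired Wilcoxon tests on PC1 per timepoint."""
    out: dict = {}
    X1, y1 = training_frame(hm, cohort=1)
    Xs1 = X1[sig.feature_ids].to_numpy(float)
    pca = mo.pca_fit(Xs1, n_components=2)
    out["pca"] = pca
    out["anosim_c1"] = mo.anosim(Xs1, y1.to_numpy(), n_perm=cfg.n_permutations,
                                 seed=cfg.seed)
    X2, y2 = training_frame(hm, cohort=2)
    out["anosim_c2"] = mo.anosim(X2[sig.feature_ids].to_numpy(float), y2.to_numpy(),
                                 n_perm=cfg.n_permutations, seed=cfg.seed)
    out["scores_c1"] = pd.DataFrame(pca.scores, index=X1.index, columns=["PC1", "PC2"])
    out["scores_c2"] = pd.DataFrame(
        mo.pca_project(pca, X2[sig.feature_ids].to_numpy(float)),
        index=X2.index, columns=["PC1", "PC2"])

    if followups is not None and fu_meta is not None:
        meta = hm.sample_meta
        fu_vals = prepare_followups(hm, followups).loc[sig.feature_ids].T
        proj = mo.pca_project(pca, fu_vals.to_numpy(float))
        fu_scores = pd.DataFrame(proj, index=fu_vals.index, columns=["PC1", "PC2"])
        fu_scores["subject_id"] = fu_meta.df.loc[fu_scores.index, "subject_id"]
        fu_scores["timepoint_months"] = fu_meta.df.loc[fu_scores.index, "timepoint_months"]
        base = meta[(meta["treated"]) & (meta["timepoint_months"] == 0)]
        base_scores = out["scores_c1"].loc[[i for i in base.index if i in out["scores_c1"].index]]
        base_pc1 = pd.Series(base_scores["PC1"].to_numpy(),
                             index=meta.loc[base_scores.index, "subject_id"])
        wilcox = {}
        for tp, grp in fu_scores.groupby("timepoint_months"):
            paired = grp.set_index("subject_id")["PC1"]
            common = base_pc1.index.intersection(paired.index)
            wilcox[float(tp)] = mo.paired_wilcoxon(base_pc1.loc[common].to_numpy(),
                                                   paired.loc[common].to_numpy())
        out["wilcoxon_pc1"] = wilcox
        out["scores_followup"] = fu_scores
    return out


def run_foldchanges(hm: hz.HarmonizedMatrix, sig: sg.Signature) -> pd.DataFrame:
    """Sex-adjusted log2 fold changes (PMS - RRMS) per selected feature and
    cohort, as in the per-feature characterization table."""
    rows = []
    for cohort in (1, 2):
        X, y = training_frame(hm, cohort=cohort)
        sex = hm.sample_meta.loc[X.index, "sex"]
        for fid in sig.feature_ids:
            est, p, sex_p = mo.adjusted_log2fc(X[fid].to_numpy(float),
                                               y.to_numpy(), sex.to_numpy())
            rows.append(dict(feature_id=fid, cohort=cohort, log2fc=est,
                             p_value=p, sex_p=sex_p))
    return pd.DataFrame(rows)


def run_associations(clinical: pd.DataFrame, levels: pd.DataFrame,
                     sex_by_subject: pd.Series) -> tuple[pd.DataFrame, list[str]]:
    """Multilevel associations of each planted/selected metabolite with each
    clinical measure over visits, plus the Spearman cluster order of the
    strength profiles.

    ``levels`` is indexed by (subject_id, timepoint_months) with one column
    per metabolite; ``clinical`` has subject_id/timepoint_months columns plus
    one column per measure.
    """
    clin = clinical.set_index(["subject_id", "timepoint_months"])
    measures = list(clin.columns)
    results = []
    idx = levels.index.intersection(clin.index)
    subj = idx.get_level_values(0)
    time = idx.get_level_values(1).astype(float)
    sex = sex_by_subject.loc[subj].to_numpy()
    for fid in levels.columns:
        for measure in measures:
            res = mo.clinical_association(
                levels.loc[idx, fid].to_numpy(float), clin.loc[idx, measure].to_numpy(float),
                time.to_numpy(), sex, subj.to_numpy(), metabolite=fid, measure=measure)
            results.append(res)
    strengths = mo.association_strengths(results)
    order = mo.spearman_hclust(strengths.dropna(how="any")) if len(strengths) >= 2 else list(strengths.index)
    return strengths, order
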