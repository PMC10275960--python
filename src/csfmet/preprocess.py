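"""Per-cohort post-quantification filtering and run-order normalization.

Fixed stage order (the output feature set shrinks monotonically):

1. blank-based contaminant removal — keep a feature only when its mean QC
   intensity is at least ``ratio_min`` (default 10) times its mean blank
   intensity; features absent from every blank are kept;
2. dilution-series filter — keep features whose raw intensity shows a
   positive Pearson correlation with injected volume at two-sided p < 0.05;
3. log2 transform;
4. QC-anchored LOESS run-order normalization (span 0.2, local linear);
5. QC CV filter — keep features whose de-logged QC coefficient of variation
   is strictly below 0.20.

A TIC (total ion count) report flags suspect injections but never removes
them.  All functions operate on a single cohort's injections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import FeatureTable, InjectionMeta


@dataclass
class PreprocessReport:
    """Per-filter removals and per-stage diagnostics."""

    stage: str
    removed: list[str] = field(default_factory=list)
    flagged: list[str] = field(default_factory=list)
    details: pd.DataFrame | None = None

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def _cohort_of(table: FeatureTable, meta: InjectionMeta) -> int:
    cohorts = meta.df.loc[table.injection_ids, "cohort"].unique()
    if len(cohorts) != 1:
        raise ValueError("table spans more than one cohort; preprocess per cohort")
    return int(cohorts[0])


def remove_blank_contaminants(table: FeatureTable, meta: InjectionMeta,
                              ratio_min: float = 10.0) -> tuple[FeatureTable, PreprocessReport]:
    """Drop features whose QC signal is not well above blank background."""
    if table.scale != "raw":
        raise ValueError("blank filter operates on raw intensities")
    cohort = _cohort_of(table, meta)
    qc_ids = [i for i in meta.qc(cohort).index if i in table.values.columns]
    blank_ids = [i for i in meta.blank(cohort).index if i in table.values.columns]
    if not qc_ids:
        raise ValueError("no QC injections: blank ratio undefined")
    if not blank_ids:
        raise ValueError("no blank injections present")
    qc_mean = table.values[qc_ids].mean(axis=1)
    blank_mean = table.values[blank_ids].mean(axis=1)  # NaN if absent in all blanks
    keep = blank_mean.isna() | (qc_mean >= ratio_min * blank_mean)
    removed = list(table.features.index[~keep])
    report = PreprocessReport(
        "blank_filter", removed=removed,
        details=pd.DataFrame({"qc_mean": qc_mean, "blank_mean": blank_mean}))
    return table.select_features(table.features.index[keep]), report


def filter_by_dilution(table: FeatureTable, meta: InjectionMeta,
                       p_max: float = 0.05) -> tuple[FeatureTable, PreprocessReport]:
    """Keep features positively Pearson-correlated with the dilution volumes
    (two-sided p below ``p_max``); constant features are removed."""
    if table.scale != "raw":
        raise ValueError("dilution filter operates on raw intensities")
    cohort = _cohort_of(table, meta)
    dil = meta.dilution(cohort)
    dil = dil[dil.index.isin(table.values.columns)]
    if dil["dilution_volume"].nunique() < 3:
        raise ValueError("need >= 3 dilution injections with distinct volumes")
    vols = dil["dilution_volume"].to_numpy(float)
    sub = table.values[list(dil.index)].to_numpy(float)

    keep = np.zeros(sub.shape[0], bool)
    rs = np.full(sub.shape[0], np.nan)
    ps = np.full(sub.shape[0], np.nan)
    for i, row in enumerate(sub):
        ok = np.isfinite(row)
        if ok.sum() < 3 or np.ptp(row[ok]) == 0:
            continue  # undefined correlation -> removed
        r, p = stats.pearsonr(row[ok], vols[ok])
        rs[i], ps[i] = r, p
        keep[i] = (r > 0) and (p < p_max)
    removed = list(table.features.index[~keep])
    report = PreprocessReport(
        "dilution_filter", removed=removed,
        details=pd.DataFrame({"r": rs, "p": ps}, index=table.features.index))
    return table.select_features(table.features.index[keep]), report


def log2_transform(table: FeatureTable) -> FeatureTable:
    """Variance-stabilizing log2; missing entries stay missing."""
    if table.scale != "raw":
        raise ValueError("table already log2-scaled")
    vals = table.values.to_numpy(float)
    bad = np.isfinite(vals) & (vals <= 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive intensity at feature {table.feature_ids[i]}, "
            f"injection {table.injection_ids[j]}")
    out = table.copy()
    out.values = pd.DataFrame(np.log2(vals), index=table.values.index,
                              columns=table.values.columns)
    out.scale = "log2"
    return out


def _loess_eval(x_fit: np.ndarray, y_fit: np.ndarray, x_eval: np.ndarray,
                span: float) -> np.ndarray:
    """Degree-1 LOESS through (x_fit, y_fit), evaluated at x_eval with linear
    extrapolation beyond the fitted range.

    The effective span is floored so every local fit sees at least three
    points (a degree-1 fit needs two; three keeps it stable with few QCs).
    """
    n = len(x_fit)
    frac = max(span, min(1.0, 3.0 / n))
    fitted = lowess(y_fit, x_fit, frac=frac, it=0, return_sorted=True)
    xs, ys = fitted[:, 0], fitted[:, 1]
    out = np.interp(x_eval, xs, ys)
    # linear extrapolation from the terminal fitted segments
    if len(xs) >= 2:
        lo = x_eval < xs[0]
        hi = x_eval > xs[-1]
        if lo.any():
            slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
            out[lo] = ys[0] + slope * (x_eval[lo] - xs[0])
        if hi.any():
            slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
            out[hi] = ys[-1] + slope * (x_eval[hi] - xs[-1])
    return out


def loess_runorder_normalize(table: FeatureTable, meta: InjectionMeta,
                             span: float = 0.2) -> tuple[FeatureTable, PreprocessReport]:
    """Remove run-order intensity drift, feature by feature.

    A LOESS curve is fitted to each feature's QC log2 intensities against
    injection order and evaluated at every injection's order; the fitted
    value is subtracted and the feature's QC mean added back, so QC levels
    become flat around their mean.  Features with fewer than five QC
    measurements pass through unchanged and are flagged.
    """
    if table.scale != "log2":
        raise ValueError("LOESS normalization expects a log2 table")
    cohort = _cohort_of(table, meta)
    qc = meta.qc(cohort)
    qc_ids = [i for i in qc.index if i in table.values.columns]
    if len(qc_ids) < 5:
        raise ValueError("need >= 5 QC injections for drift correction")
    orders = meta.df.loc[table.injection_ids, "injection_order"].to_numpy(float)
    qc_orders = meta.df.loc[qc_ids, "injection_order"].to_numpy(float)

    vals = table.values.to_numpy(float).copy()
    qc_idx = [table.injection_ids.index(i) for i in qc_ids]
    flagged = []
    for i, fid in enumerate(table.feature_ids):
        y_qc = vals[i, qc_idx]
        ok = np.isfinite(y_qc)
        if ok.sum() < 5:
            flagged.append(fid)
            continue
        curve = _loess_eval(qc_orders[ok], y_qc[ok], orders, span)
        vals[i, :] = vals[i, :] - curve + np.mean(y_qc[ok])
    out = table.copy()
    out.values = pd.DataFrame(vals, index=table.values.index, columns=table.values.columns)
    return out, PreprocessReport("loess_normalize", flagged=flagged)


def qc_cv_filter(table: FeatureTable, meta: InjectionMeta,
                 cv_max: float = 0.20) -> tuple[FeatureTable, PreprocessReport]:
    """Keep features whose de-logged QC coefficient of variation is < cv_max
    (strict); features with no QC measurements are removed and flagged."""
    if table.scale != "log2":
        raise ValueError("CV filter expects a log2 table (CV uses de-logged values)")
    cohort = _cohort_of(table, meta)
    qc_ids = [i for i in meta.qc(cohort).index if i in table.values.columns]
    if len(qc_ids) < 3:
        raise ValueError("need >= 3 QC injections for the CV filter")
    delog = np.exp2(table.values[qc_ids].to_numpy(float))
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN QC rows
        mean = np.nanmean(delog, axis=1)
        sd = np.nanstd(delog, axis=1, ddof=1)
    n_ok = np.isfinite(delog).sum(axis=1)
    cv = np.where(n_ok >= 2, sd / mean, np.nan)
    keep = cv < cv_max  # NaN compares False -> removed
    removed = list(table.features.index[~keep])
    flagged = list(table.features.index[n_ok == 0])
    report = PreprocessReport("cv_filter", removed=removed, flagged=flagged,
                              details=pd.DataFrame({"qc_cv": cv}, index=table.features.index))
    return table.select_features(table.features.index[keep]), report


def tic_report(table: FeatureTable, meta: InjectionMeta,
               mad_factor: float = 3.0) -> PreprocessReport:
    """Total ion count per injection; flag |TIC - median| > mad_factor * MAD.

    Report-only: outliers are surfaced for inspection, never removed.
    """
    vals = table.values.to_numpy(float)
    if table.scale == "log2":
        vals = np.exp2(vals)
    tic = np.nansum(vals, axis=0)
    med = np.median(tic)
    mad = np.median(np.abs(tic - med))
    if mad == 0:  # degenerate spread: any deviation from the median is suspect
        flagged_mask = tic != med
    else:
        flagged_mask = np.abs(tic - med) > mad_factor * mad
    inj = np.array(table.injection_ids)
    return PreprocessReport("tic_report", flagged=list(inj[flagged_mask]),
                            details=pd.DataFrame({"tic": tic}, index=inj))


def preprocess_cohort(table: FeatureTable, meta: InjectionMeta,
                      blank_ratio_min: float = 10.0, dilution_p_max: float = 0.05,
                      loess_span: float = 0.2, cv_max: float = 0.20,
                      tic_mad_factor: float = 3.0
                      ) -> tuple[FeatureTable, list[PreprocessReport]]:
    """Run the full per-cohort pipeline in its fixed order."""
    reports = [tic_report(table, meta, tic_mad_factor)]
    table, rep = remove_blank_contaminants(table, meta, blank_ratio_min)
    reports.append(rep)
    table, rep = filter_by_dilution(table, meta, dilution_p_max)
    reports.append(rep)
    table = log2_transform(table)
    table, rep = loess_runorder_normalize(table, meta, loess_span)
    reports.append(rep)
    table, rep = qc_cv_filter(table, meta, cv_max)
    reports.append(rep)
    return table, reports


def report_frame(reports: list[PreprocessReport]) -> pd.DataFrame:
    """Flat summary of removals/flags per stage (one row per feature event)."""
    rows = []
    for rep in reports:
        for fid in rep.removed:
            rows.append(dict(stage=rep.stage, feature_id=fid, event="removed"))
        for fid in rep.flagged:
            rows.append(dict(stage=rep.stage, feature_id=fid, event="flagged"))
    return pd.DataFrame(rows, columns=["stage", "feature_id", "event"])
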