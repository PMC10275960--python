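"""Cross-cohort feature matching and the analysis-ready harmonized matrix.

Features are matched across the two cohorts within +-2.5 ppm in mass and
+-5 s in retention time (same ion mode), one-to-one, greedily by the
combined normalized distance.  Matches whose mean log2 intensity difference
deviates from the average difference by one standard deviation or more are
discarded.  Features significantly correlated with age in cohort-1 healthy
controls are excluded, features must be present in >= 90% of study samples
in both cohorts, remaining missing values are imputed by the within-cohort
feature mean, and every feature is centered to mean zero within each cohort.
The cohort-1 feature id is the canonical identity of a matched feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import FeatureTable, InjectionMeta


@dataclass
class FeatureMatch:
    feature_id_c1: str
    feature_id_c2: str
    ppm_delta: float       # signed, (mz1 - mz2)/mz1 * 1e6
    rt_delta: float        # signed seconds, rt1 - rt2
    intensity_delta: float # mean log2 intensity difference, cohort1 - cohort2


def matches_frame(matches: list[FeatureMatch]) -> pd.DataFrame:
    return pd.DataFrame([m.__dict__ for m in matches],
                        columns=["feature_id_c1", "feature_id_c2", "ppm_delta",
                                 "rt_delta", "intensity_delta"])


@dataclass
class HarmonizedMatrix:
    """Matched, filtered, imputed, within-cohort-centered two-cohort matrix.

    ``values`` is features x study-samples (canonical cohort-1 feature ids);
    ``sample_meta`` carries the per-sample annotations including cohort.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    matches: pd.DataFrame
    age_removed: list[str] = field(default_factory=list)
    presence_removed: list[str] = field(default_factory=list)
    #: per-feature pre-centering means, columns "c1"/"c2"; needed to place
    #: later samples (follow-ups) on the cohort-1 centered scale
    cohort_means: pd.DataFrame | None = None

    def cohort_samples(self, cohort: int) -> list[str]:
        return list(self.sample_meta.index[self.sample_meta["cohort"] == cohort])

    def matrix(self, cohort: int | None = None, groups=None) -> tuple[np.ndarray, pd.DataFrame]:
        """(samples x features array, matching sample annotations)."""
        meta = self.sample_meta
        if cohort is not None:
            meta = meta[meta["cohort"] == cohort]
        if groups is not None:
            meta = meta[meta["group"].isin(groups)]
        return self.values[meta.index].to_numpy(float).T, meta


def ppm_delta(mz1: float, mz2: float) -> float:
    return (mz1 - mz2) / mz1 * 1e6


def match_features(t1: FeatureTable, t2: FeatureTable, ppm_max: float = 2.5,
                   rt_max_s: float = 5.0) -> list[FeatureMatch]:
    """One-to-one cross-cohort matching inside the mass/RT windows.

    Candidate pairs share the ion mode and satisfy both windows; assignment
    is greedy in ascending combined score ``|ppm|/ppm_max + |drt|/rt_max_s``
    (deterministic tie-break on the id pair).  Mean log2 intensity
    difference (cohort1 - cohort2) is recorded for each accepted match.
    """
    if t1.scale != "log2" or t2.scale != "log2":
        raise ValueError("matching expects log2-scale tables")
    cand = []
    f2_by_mode = {m: t2.features[t2.features["ion_mode"] == m] for m in ("positive", "negative")}
    mean1 = t1.values.mean(axis=1)
    mean2 = t2.values.mean(axis=1)
    for fid1, row1 in t1.features.iterrows():
        pool = f2_by_mode[row1["ion_mode"]]
        dppm = (row1["mz"] - pool["mz"]) / row1["mz"] * 1e6
        drt = row1["rt"] - pool["rt"]
        ok = (dppm.abs() <= ppm_max) & (drt.abs() <= rt_max_s)
        for fid2 in pool.index[ok]:
            score = abs(dppm[fid2]) / ppm_max + abs(drt[fid2]) / rt_max_s
            cand.append((score, fid1, fid2, dppm[fid2], drt[fid2]))
    cand.sort(key=lambda c: (c[0], c[1], c[2]))
    used1, used2 = set(), set()
    out = []
    for score, fid1, fid2, dp, dr in cand:
        if fid1 in used1 or fid2 in used2:
            continue
        used1.add(fid1)
        used2.add(fid2)
        out.append(FeatureMatch(fid1, fid2, float(dp), float(dr),
                                float(mean1[fid1] - mean2[fid2])))
    out.sort(key=lambda m: m.feature_id_c1)
    return out


def intensity_consistency_filter(matches: list[FeatureMatch]) -> list[FeatureMatch]:
    """Keep matches whose intensity difference sits within one standard
    deviation of the mean difference (computed once over all input matches).

    Degenerate case: sd = 0 (all differences equal) keeps everything.
    """
    if len(matches) < 3:
        warnings.warn("fewer than 3 matches: intensity consistency filter skipped")
        return list(matches)
    d = np.array([m.intensity_delta for m in matches])
    mean, sd = d.mean(), d.std(ddof=1)
    if sd == 0:
        return list(matches)
    return [m for m, di in zip(matches, d) if abs(di - mean) < sd]


def age_filter(table: FeatureTable, meta: InjectionMeta,
               p_max: float = 0.05) -> tuple[list[str], FeatureTable]:
    """Remove features whose log2 level correlates with age in cohort-1
    healthy controls (two-sided Pearson p < p_max).  Constant features have
    an undefined correlation and are kept."""
    hc = meta.study(cohort=1, groups=["HC"])
    hc = hc[hc.index.isin(table.values.columns)]
    if len(hc) < 10:
        raise ValueError("need >= 10 cohort-1 healthy controls with ages")
    ages = hc["age"].to_numpy(float)
    removed = []
    for fid in table.feature_ids:
        y = table.values.loc[fid, hc.index].to_numpy(float)
        ok = np.isfinite(y) & np.isfinite(ages)
        if ok.sum() < 3 or np.ptp(y[ok]) == 0:
            continue
        _, p = stats.pearsonr(y[ok], ages[ok])
        if p < p_max:
            removed.append(fid)
    kept = table.select_features([f for f in table.feature_ids if f not in set(removed)])
    return removed, kept


def presence_filter(t1: FeatureTable, t2: FeatureTable, meta: InjectionMeta,
                    matches: pd.DataFrame, min_frac: float = 0.90) -> list[str]:
    """Canonical ids of matched features present (non-missing) in at least
    ``min_frac`` of study samples within each cohort separately."""
    kept = []
    s1 = [i for i in meta.study(cohort=1).index if i in t1.values.columns]
    s2 = [i for i in meta.study(cohort=2).index if i in t2.values.columns]
    for _, m in matches.iterrows():
        frac1 = t1.values.loc[m.feature_id_c1, s1].notna().mean()
        frac2 = t2.values.loc[m.feature_id_c2, s2].notna().mean()
        if frac1 >= min_frac and frac2 >= min_frac:
            kept.append(m.feature_id_c1)
    return kept


def impute_and_center(t1: FeatureTable, t2: FeatureTable, meta: InjectionMeta,
                      matches: pd.DataFrame, age_removed: list[str] | None = None,
                      presence_removed: list[str] | None = None) -> HarmonizedMatrix:
    """Build the analysis-ready matrix over the given (filtered) matches:
    missing study-sample entries are imputed by the within-cohort feature
    mean, then every feature is centered to mean zero within each cohort."""
    s1 = [i for i in meta.study(cohort=1).index if i in t1.values.columns]
    s2 = [i for i in meta.study(cohort=2).index if i in t2.values.columns]
    ids1 = matches["feature_id_c1"].tolist()
    ids2 = matches["feature_id_c2"].tolist()

    blocks, mean_cols = [], {}
    for key, tab, ids, samples in (("c1", t1, ids1, s1), ("c2", t2, ids2, s2)):
        sub = tab.values.loc[ids, samples].astype(float)
        means = sub.mean(axis=1)
        if means.isna().any():
            bad = means.index[means.isna()][0]
            raise ValueError(f"feature {bad} entirely missing within a cohort")
        sub = sub.apply(lambda col: col.fillna(means), axis=0)
        sub = sub.sub(sub.mean(axis=1), axis=0)  # imputed entries become exactly 0
        sub.index = pd.Index(ids1, name="feature_id")  # canonical id = cohort-1 id
        blocks.append(sub)
        mean_cols[key] = means.to_numpy()
    values = pd.concat(blocks, axis=1)
    sample_meta = meta.df.loc[s1 + s2].copy()
    return HarmonizedMatrix(values=values, sample_meta=sample_meta, matches=matches,
                            age_removed=list(age_removed or []),
                            presence_removed=list(presence_removed or []),
                            cohort_means=pd.DataFrame(mean_cols, index=pd.Index(ids1, name="feature_id")))


def harmonize(t1: FeatureTable, t2: FeatureTable, meta: InjectionMeta,
              ppm_max: float = 2.5, rt_max_s: float = 5.0,
              age_p_max: float = 0.05, presence_min: float = 0.90
              ) -> HarmonizedMatrix:
    """Full harmonization: match -> intensity consistency -> age filter ->
    presence filter -> impute & center."""
    matches = intensity_consistency_filter(match_features(t1, t2, ppm_max, rt_max_s))
    mdf = matches_frame(matches)
    t1m = t1.select_features(mdf["feature_id_c1"].tolist())
    age_removed, _ = age_filter(t1m, meta, age_p_max)
    mdf = mdf[~mdf["feature_id_c1"].isin(age_removed)].reset_index(drop=True)
    kept = set(presence_filter(t1, t2, meta, mdf, presence_min))
    presence_removed = [f for f in mdf["feature_id_c1"] if f not in kept]
    mdf = mdf[mdf["feature_id_c1"].isin(kept)].reset_index(drop=True)
    return impute_and_center(t1, t2, meta, mdf, age_removed, presence_removed)
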