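"""Synthetic two-cohort LC-MS metabolomics data with known ground truth.

The generator emulates the structure of a two-cohort CSF metabolomics study
of multiple-sclerosis phenotypes: healthy controls (HC), relapsing-remitting
(RRMS) and progressive (PMS) patients in two independently acquired cohorts,
with planted phenotype-discriminatory features, age-dependent confounder
features, sex effects, per-cohort systematic shifts, run-order intensity
drift, QC / blank / two-fold-dilution injections, missingness, and treated
PMS patients re-sampled at 3/6/12 months whose planted-feature signature
drifts toward the RRMS distribution.

Intensity model (log2 scale), for feature *f* and study injection *j*::

    log2 I_fj = mu_f + delta_f * I(PMS) + a_f * age_j + s_f * I(male)
                + c_f * I(cohort 2) + g_f(order_j) + eps,   eps ~ N(0, sigma^2)

The raw table is ``2 ** log2`` with missingness applied to study samples.
QC injections measure the pooled sample (per-feature pool level + drift +
small noise); blanks sit ~10 log2 units below the pool except for planted
contaminants; dilution injections scale linearly with injected volume.

m/z values are laid out on a jittered 0.05 Da grid so distinct features are
never within the cross-cohort ppm window of one another; cohort-2
counterparts of true-match features are jittered inside the +-2.5 ppm /
+-5 s windows, decoy counterparts are pushed outside (half in mass, half in
retention time).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import FeatureTable, InjectionMeta, write_feature_table, write_injection_meta

_STREAMS = {
    "catalog": 0,
    "subjects": 1,
    "values_c1": 2,
    "values_c2": 3,
    "missing": 4,
    "drift": 5,
    "longitudinal": 6,
    "clinical": 7,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named, independent sub-stream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class SynthConfig:
    """Generator settings; the defaults reproduce the study's structure
    (group sizes per its two cohorts, dilution series 0.5-32 uL, QC/blank
    every 8th injection, 0/3/6/12-month follow-ups of treated PMS patients).
    """

    # cohort 1 / cohort 2 group sizes (HC, RRMS, PMS)
    n_hc_c1: int = 49
    n_rrms_c1: int = 39
    n_pms_c1: int = 35
    n_hc_c2: int = 10
    n_rrms_c2: int = 30
    n_pms_c2: int = 16
    # feature catalog
    n_features: int = 600          # shared (truly matching) features
    n_planted: int = 10            # phenotype-discriminatory features
    effect_log2: float = 0.6       # |PMS - RRMS| log2 effect, alternating sign
    age_frac: float = 0.10         # fraction of age-dependent features
    age_slope: float = 0.03        # log2 units per year
    sex_frac: float = 0.05
    sex_effect: float = 0.3        # log2 units (male - female)
    contam_frac: float = 0.04      # blank contaminants, per cohort
    decoy_frac: float = 0.10       # cross-cohort decoy features (outside windows)
    blank_absent_frac: float = 0.30
    # nuisance structure
    cohort_shift_sd: float = 0.3   # tau: per-feature systematic cohort-2 shift
    drift_amplitude: float = 0.3   # max sinusoidal run-order drift (log2)
    sigma: float = 0.5             # residual sd (log2)
    qc_sigma: float = 0.1          # QC/dilution technical sd (log2)
    missing_rate: float = 0.05     # MCAR rate on study cells
    # injection layout
    qc_lead: int = 5
    blank_lead: int = 2
    qc_interval: int = 8
    dilution_volumes: Sequence[float] = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
    injection_volume: float = 10.0
    # mass / RT catalog
    mz_min: float = 70.0
    mz_grid_step: float = 0.05
    rt_min: float = 60.0
    rt_max: float = 900.0
    match_ppm_jitter: float = 1.5  # |c2 - c1| jitter for true matches (ppm)
    match_rt_jitter: float = 2.5   # seconds
    # longitudinal arm
    n_treated: int = 22
    timepoints: Sequence[int] = (0, 3, 6, 12)
    drift_frac_per_month: float = 1.0 / 12.0
    n_clinical: int = 8
    clinical_noise_sd: float = 0.5
    clinical_intercept_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        counts = [self.n_hc_c1, self.n_rrms_c1, self.n_pms_c1,
                  self.n_hc_c2, self.n_rrms_c2, self.n_pms_c2, self.n_features]
        if any(c <= 0 for c in counts):
            raise ValueError("all group/feature counts must be positive")
        if self.n_planted > self.n_features:
            raise ValueError("n_planted exceeds n_features")
        if not 0 <= self.drift_frac_per_month <= 1:
            raise ValueError("drift_frac_per_month must lie in [0, 1]")
        if not np.isfinite(self.effect_log2):
            raise ValueError("effect size must be finite")
        if self.n_treated > self.n_pms_c1:
            raise ValueError("n_treated exceeds cohort-1 PMS count")


@dataclass
class SynthTruth:
    """Ground truth for one generated data set."""

    planted: pd.DataFrame          # feature_id (c1), effect (log2, PMS-RRMS)
    age_dependent: pd.DataFrame    # feature_id (c1), slope (log2/year)
    matches: pd.DataFrame          # feature_id_c1, feature_id_c2 (true pairs)
    decoys: pd.DataFrame           # feature_id_c1, feature_id_c2, kind
    contaminants: dict             # cohort -> list of feature ids
    drift: pd.DataFrame            # cohort, feature_id, amplitude, period, phase
    params: pd.DataFrame           # per shared feature: mu, delta, age_slope, sex_effect, cohort_shift
    clinical_coefs: pd.DataFrame | None = None   # measure, feature_id, coefficient
    longitudinal_levels: pd.DataFrame | None = None  # subject, timepoint, planted log2 levels

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.planted.to_csv(out / "planted_features.tsv", sep="\t", index=False)
        self.age_dependent.to_csv(out / "age_features.tsv", sep="\t", index=False)
        self.matches.to_csv(out / "true_matches.tsv", sep="\t", index=False)
        self.decoys.to_csv(out / "decoys.tsv", sep="\t", index=False)
        self.drift.to_csv(out / "drift.tsv", sep="\t", index=False)
        pd.DataFrame({"cohort": [c for c, ids in self.contaminants.items() for _ in ids],
                      "feature_id": [i for ids in self.contaminants.values() for i in ids]}
                     ).to_csv(out / "contaminants.tsv", sep="\t", index=False)
        if self.clinical_coefs is not None:
            self.clinical_coefs.to_csv(out / "clinical_truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

def _build_catalog(cfg: SynthConfig, rng: np.random.Generator) -> dict:
    n_decoy = int(round(cfg.decoy_frac * cfg.n_features))
    n_total = cfg.n_features + n_decoy
    # jittered grid keeps every pair of distinct features > 2.5 ppm apart
    ks = rng.permutation(n_total * 2)[:n_total]
    mz = cfg.mz_min + cfg.mz_grid_step * ks + rng.uniform(-0.005, 0.005, n_total)
    rt = rng.uniform(cfg.rt_min, cfg.rt_max, n_total)
    ion_mode = rng.choice(["positive", "negative"], n_total)
    mu = rng.uniform(14.0, 24.0, n_total)

    shared = np.arange(cfg.n_features)
    decoy = np.arange(cfg.n_features, n_total)

    # role assignment among shared features (mutually disjoint by default)
    roles = rng.permutation(cfg.n_features)
    n_age = int(round(cfg.age_frac * cfg.n_features))
    n_sex = int(round(cfg.sex_frac * cfg.n_features))
    planted = np.sort(roles[:cfg.n_planted])
    age_dep = np.sort(roles[cfg.n_planted:cfg.n_planted + n_age])
    sex_dep = np.sort(roles[cfg.n_planted + n_age:cfg.n_planted + n_age + n_sex])

    delta = np.zeros(n_total)
    signs = np.where(np.arange(len(planted)) % 2 == 0, 1.0, -1.0)
    delta[planted] = signs * cfg.effect_log2
    a = np.zeros(n_total)
    a[age_dep] = rng.choice([-1.0, 1.0], n_age) * cfg.age_slope
    s = np.zeros(n_total)
    s[sex_dep] = rng.choice([-1.0, 1.0], n_sex) * cfg.sex_effect
    c_shift = rng.normal(0.0, cfg.cohort_shift_sd, n_total)

    # cohort-2 m/z and RT: inside the match windows for shared features,
    # outside (mass or RT) for decoys
    ppm_jit = rng.uniform(-cfg.match_ppm_jitter, cfg.match_ppm_jitter, n_total)
    rt_jit = rng.uniform(-cfg.match_rt_jitter, cfg.match_rt_jitter, n_total)
    mz2 = mz * (1.0 + ppm_jit * 1e-6)
    rt2 = rt + rt_jit
    decoy_kind = np.array([""] * n_total, dtype=object)
    for i, f in enumerate(decoy):
        sgn = rng.choice([-1.0, 1.0])
        if i % 2 == 0:  # mass decoy: 6-20 ppm off (still far from grid neighbors)
            mz2[f] = mz[f] * (1.0 + sgn * rng.uniform(6.0, 20.0) * 1e-6)
            decoy_kind[f] = "mz"
        else:           # RT decoy: 10-25 s off
            rt2[f] = rt[f] + sgn * rng.uniform(10.0, 25.0)
            decoy_kind[f] = "rt"

    blank_absent = rng.random(n_total) < cfg.blank_absent_frac
    n_contam = int(round(cfg.contam_frac * n_total))
    eligible = np.setdiff1d(np.arange(n_total), planted)
    contam_c1 = rng.choice(eligible, n_contam, replace=False)
    contam_c2 = rng.choice(eligible, n_contam, replace=False)

    return dict(n_total=n_total, mz=mz, rt=rt, mz2=mz2, rt2=rt2, ion_mode=ion_mode,
                mu=mu, delta=delta, age_slope=a, sex_effect=s, cohort_shift=c_shift,
                shared=shared, decoy=decoy, decoy_kind=decoy_kind, planted=planted,
                age_dep=age_dep, sex_dep=sex_dep, blank_absent=blank_absent,
                contam={1: contam_c1, 2: contam_c2})


def _feature_ids(cohort: int, n: int) -> list[str]:
    return [f"C{cohort}_F{i:04d}" for i in range(n)]


# ---------------------------------------------------------------------------
# subjects and injection layout
# ---------------------------------------------------------------------------

_AGE_PARAMS = {  # (mean, sd) per cohort and group; HC cohort 1 is uniform 18-74
    (1, "RRMS"): (33.0, 9.10), (1, "PMS"): (50.0, 9.53),
    (2, "HC"): (39.0, 13.1), (2, "RRMS"): (39.0, 10.6), (2, "PMS"): (58.0, 9.3),
}
_FEMALE_FRAC = {
    (1, "HC"): 28 / 49, (1, "RRMS"): 27 / 39, (1, "PMS"): 22 / 35,
    (2, "HC"): 6 / 10, (2, "RRMS"): 21 / 30, (2, "PMS"): 10 / 16,
}


def _make_subjects(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    sizes = {(1, "HC"): cfg.n_hc_c1, (1, "RRMS"): cfg.n_rrms_c1, (1, "PMS"): cfg.n_pms_c1,
             (2, "HC"): cfg.n_hc_c2, (2, "RRMS"): cfg.n_rrms_c2, (2, "PMS"): cfg.n_pms_c2}
    for (cohort, group), n in sizes.items():
        if cohort == 1 and group == "HC":
            ages = rng.uniform(18.0, 74.0, n)  # HC span the full adult range
        else:
            m, sd = _AGE_PARAMS[(cohort, group)]
            ages = np.clip(rng.normal(m, sd, n), 18.0, 85.0)
        female = rng.random(n) < _FEMALE_FRAC[(cohort, group)]
        for i in range(n):
            rows.append(dict(subject_id=f"C{cohort}_{group}{i + 1:02d}", cohort=cohort,
                             group=group, age=float(ages[i]),
                             sex="F" if female[i] else "M", treated=False))
    subj = pd.DataFrame(rows)
    treated_ids = subj[(subj.cohort == 1) & (subj.group == "PMS")].subject_id.iloc[:cfg.n_treated]
    subj.loc[subj.subject_id.isin(treated_ids), "treated"] = True
    return subj


def _layout(cfg: SynthConfig, cohort: int, subjects: pd.DataFrame,
            rng: np.random.Generator) -> pd.DataFrame:
    """Injection sequence: lead QCs, lead blanks, dilution series, then study
    samples in randomized order with a QC and a blank every ``qc_interval``."""
    rows = []
    order = 0

    def add(kind, **kw):
        nonlocal order
        order += 1
        row = dict(injection_id=f"C{cohort}_I{order:03d}", cohort=cohort,
                   sample_type=kind, injection_order=order, subject_id="pool",
                   group=None, dilution_volume=None, age=np.nan, sex=None,
                   timepoint_months=np.nan, treated=False)
        row.update(kw)
        rows.append(row)

    for _ in range(cfg.qc_lead):
        add("qc")
    for _ in range(cfg.blank_lead):
        add("blank", subject_id="blank")
    for v in cfg.dilution_volumes:
        add("dilution", dilution_volume=float(v))
    study = subjects[subjects.cohort == cohort].sample(frac=1.0, random_state=np.random.RandomState(rng.integers(2**31)))
    for i, (_, s) in enumerate(study.iterrows()):
        if i > 0 and i % cfg.qc_interval == 0:
            add("qc")
            add("blank", subject_id="blank")
        add("study", subject_id=s.subject_id, group=s.group, age=s.age, sex=s.sex,
            timepoint_months=0.0 if s.treated else np.nan, treated=bool(s.treated))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# intensity generation
# ---------------------------------------------------------------------------

def _drift_params(cfg: SynthConfig, n_feat: int, n_inj: int, rng: np.random.Generator):
    amp = rng.uniform(0.0, cfg.drift_amplitude, n_feat)
    period = rng.uniform(0.7, 1.3, n_feat) * n_inj
    phase = rng.uniform(0.0, 2 * np.pi, n_feat)
    return amp, period, phase


def _drift_matrix(amp, period, phase, orders):
    return amp[:, None] * np.sin(2 * np.pi * orders[None, :] / period[:, None] + phase[:, None])


def _cohort_values(cfg: SynthConfig, cat: dict, cohort: int, layout: pd.DataFrame,
                   rng: np.random.Generator, drift_rng: np.random.Generator):
    n_feat = cat["n_total"]
    n_inj = len(layout)
    orders = layout["injection_order"].to_numpy(float)
    mu = cat["mu"]
    shift = cat["cohort_shift"] if cohort == 2 else np.zeros(n_feat)
    amp, period, phase = _drift_params(cfg, n_feat, n_inj, drift_rng)
    drift = _drift_matrix(amp, period, phase, orders)

    log2 = np.empty((n_feat, n_inj))
    pool = mu + shift  # pooled-QC expected level
    is_contam = np.zeros(n_feat, bool)
    is_contam[cat["contam"][cohort]] = True

    for j, (_, inj) in enumerate(layout.iterrows()):
        kind = inj.sample_type
        if kind == "study":
            eff = (mu + shift
                   + cat["delta"] * (inj.group == "PMS")
                   + cat["age_slope"] * inj.age
                   + cat["sex_effect"] * (inj.sex == "M"))
            log2[:, j] = eff + rng.normal(0.0, cfg.sigma, n_feat)
        elif kind == "qc":
            log2[:, j] = pool + rng.normal(0.0, cfg.qc_sigma, n_feat)
        elif kind == "dilution":
            base = pool + np.log2(inj.dilution_volume / cfg.injection_volume)
            base = np.where(is_contam, pool, base)  # contaminants ignore volume
            log2[:, j] = base + rng.normal(0.0, cfg.qc_sigma, n_feat)
        else:  # blank: ~1000x below pool, except contaminants at pool level
            base = np.where(is_contam, pool, pool - 10.0)
            log2[:, j] = base + rng.normal(0.0, 0.3, n_feat)
    log2 += drift
    raw = np.exp2(log2)

    # features absent from all blanks (contaminants always show in blanks)
    blank_cols = np.flatnonzero((layout.sample_type == "blank").to_numpy())
    absent = cat["blank_absent"] & ~is_contam
    raw[np.ix_(np.flatnonzero(absent), blank_cols)] = np.nan
    return raw, (amp, period, phase)


def generate_cohorts(cfg: SynthConfig) -> tuple[FeatureTable, FeatureTable, InjectionMeta, SynthTruth]:
    """Generate both cohorts (raw scale) with metadata and ground truth."""
    cfg.validate()
    cat = _build_catalog(cfg, _rng(cfg.seed, "catalog"))
    subjects = _make_subjects(cfg, _rng(cfg.seed, "subjects"))
    drift_rng = _rng(cfg.seed, "drift")
    miss_rng = _rng(cfg.seed, "missing")

    tables, layouts, drifts = {}, {}, {}
    for cohort in (1, 2):
        rng = _rng(cfg.seed, f"values_c{cohort}")
        layout = _layout(cfg, cohort, subjects, rng)
        raw, dpar = _cohort_values(cfg, cat, cohort, layout, rng, drift_rng)
        # MCAR missingness on study cells only
        study_cols = np.flatnonzero((layout.sample_type == "study").to_numpy())
        mask = miss_rng.random((raw.shape[0], len(study_cols))) < cfg.missing_rate
        raw[np.ix_(np.arange(raw.shape[0]), study_cols)] = np.where(
            mask, np.nan, raw[:, study_cols])
        ids = _feature_ids(cohort, cat["n_total"])
        feats = pd.DataFrame({
            "mz": cat["mz"] if cohort == 1 else cat["mz2"],
            "rt": cat["rt"] if cohort == 1 else cat["rt2"],
            "ion_mode": cat["ion_mode"],
        }, index=pd.Index(ids, name="feature_id"))
        values = pd.DataFrame(raw, index=feats.index, columns=layout["injection_id"].tolist())
        tables[cohort] = FeatureTable(feats, values, "raw")
        layouts[cohort] = layout
        drifts[cohort] = dpar

    meta_df = pd.concat([layouts[1], layouts[2]], ignore_index=True).set_index("injection_id")
    meta_df["dilution_volume"] = pd.to_numeric(meta_df["dilution_volume"])
    meta_df["timepoint_months"] = pd.to_numeric(meta_df["timepoint_months"])
    meta = InjectionMeta(meta_df)

    ids1 = np.array(_feature_ids(1, cat["n_total"]))
    ids2 = np.array(_feature_ids(2, cat["n_total"]))
    truth = SynthTruth(
        planted=pd.DataFrame({"feature_id": ids1[cat["planted"]],
                              "effect": cat["delta"][cat["planted"]]}),
        age_dependent=pd.DataFrame({"feature_id": ids1[cat["age_dep"]],
                                    "slope": cat["age_slope"][cat["age_dep"]]}),
        matches=pd.DataFrame({"feature_id_c1": ids1[cat["shared"]],
                              "feature_id_c2": ids2[cat["shared"]]}),
        decoys=pd.DataFrame({"feature_id_c1": ids1[cat["decoy"]],
                             "feature_id_c2": ids2[cat["decoy"]],
                             "kind": cat["decoy_kind"][cat["decoy"]]}),
        contaminants={c: list(ids1[cat["contam"][1]]) if c == 1 else list(ids2[cat["contam"][2]])
                      for c in (1, 2)},
        drift=pd.concat([
            pd.DataFrame({"cohort": c, "feature_id": (ids1 if c == 1 else ids2),
                          "amplitude": drifts[c][0], "period": drifts[c][1],
                          "phase": drifts[c][2]})
            for c in (1, 2)], ignore_index=True),
        params=pd.DataFrame({"mu": cat["mu"], "delta": cat["delta"],
                             "age_slope": cat["age_slope"], "sex_effect": cat["sex_effect"],
                             "cohort_shift": cat["cohort_shift"]},
                            index=pd.Index(ids1, name="feature_id")),
    )
    return tables[1], tables[2], meta, truth


# ---------------------------------------------------------------------------
# longitudinal follow-ups and clinical measures
# ---------------------------------------------------------------------------

def generate_longitudinal(truth: SynthTruth, cfg: SynthConfig, meta: InjectionMeta,
                          features: pd.DataFrame | None = None
                          ) -> tuple[FeatureTable, InjectionMeta]:
    """Follow-up injections for treated cohort-1 PMS patients.

    At month *m* the planted-feature mean is pulled toward RRMS:
    ``mu + delta * (1 - drift_frac_per_month * m)``; other features keep
    their baseline model.  Follow-ups emulate already drift-corrected
    re-injections: no run-order drift or missingness is added.
    """
    treated = meta.study(cohort=1)
    treated = treated[treated["treated"]]
    if treated.empty:
        raise ValueError("no treated subjects in cohort 1 PMS group")
    rng = _rng(cfg.seed, "longitudinal")
    p = truth.params
    ids = p.index.to_numpy()
    planted_mask = p.index.isin(truth.planted["feature_id"])

    follow_months = [m for m in cfg.timepoints if m != 0]
    cols, rows_meta = [], []
    values = []
    max_order = int(meta.df.loc[meta.df.cohort == 1, "injection_order"].max())
    order = max_order
    level_records = []
    for _, s in treated.sort_values("subject_id").iterrows():
        for m in follow_months:
            order += 1
            iid = f"C1_FU_{s.subject_id}_m{m:02d}"
            shrink = np.where(planted_mask, 1.0 - cfg.drift_frac_per_month * m, 1.0)
            mean = (p["mu"].to_numpy() + p["delta"].to_numpy() * shrink
                    + p["age_slope"].to_numpy() * s.age
                    + p["sex_effect"].to_numpy() * (s.sex == "M"))
            log2 = mean + rng.normal(0.0, cfg.sigma, len(ids))
            values.append(np.exp2(log2))
            cols.append(iid)
            rows_meta.append(dict(injection_id=iid, subject_id=s.subject_id, cohort=1,
                                  group="PMS", sample_type="study", dilution_volume=None,
                                  injection_order=order, age=s.age, sex=s.sex,
                                  timepoint_months=float(m), treated=True))
            level_records.append(pd.Series(log2[planted_mask],
                                           index=ids[planted_mask],
                                           name=(s.subject_id, m)))
    if features is not None:
        feats = features.loc[ids, ["mz", "rt", "ion_mode"]].copy()
    else:  # placeholder coordinates: follow-ups are projected, never re-matched
        feats = pd.DataFrame({"mz": 100.0 + 0.05 * np.arange(len(ids)), "rt": 300.0,
                              "ion_mode": "positive"},
                             index=pd.Index(ids, name="feature_id"))
    table = FeatureTable(feats, pd.DataFrame(np.column_stack(values), index=feats.index,
                                             columns=cols), "raw")
    fu_df = pd.DataFrame(rows_meta).set_index("injection_id")
    fu_df["dilution_volume"] = pd.to_numeric(fu_df["dilution_volume"])
    fu_meta = InjectionMeta(fu_df)
    lev = pd.DataFrame(level_records)
    lev.index = pd.MultiIndex.from_tuples(lev.index, names=["subject_id", "timepoint_months"])
    truth.longitudinal_levels = lev
    return table, fu_meta


_CLINICAL_MEASURES = ("EDSS", "SDMT", "6MWT", "25FWT", "FSMC_cog", "FSMC_mot",
                      "9HPT_dom", "9HPT_nondom")


def generate_clinical(truth: SynthTruth, cfg: SynthConfig,
                      baseline_levels: pd.DataFrame | None = None) -> pd.DataFrame:
    """Clinical measures for treated patients across visits.

    Each measure is a linear combination of two planted metabolite log2
    levels plus a patient random intercept and Gaussian noise; coefficients
    are recorded in ``truth.clinical_coefs``.  Requires
    :func:`generate_longitudinal` to have populated
    ``truth.longitudinal_levels`` (the baseline visit may be supplied
    separately via ``baseline_levels``, same columns).
    """
    if truth.longitudinal_levels is None:
        raise ValueError("generate_longitudinal must run before generate_clinical")
    rng = _rng(cfg.seed, "clinical")
    levels = truth.longitudinal_levels
    if baseline_levels is not None:
        levels = pd.concat([baseline_levels, levels]).sort_index()
    planted_ids = list(levels.columns)
    subjects = levels.index.get_level_values(0).unique()
    intercepts = pd.Series(rng.normal(0.0, cfg.clinical_intercept_sd, len(subjects)),
                           index=subjects)

    coef_rows, data_rows = [], []
    measures = _CLINICAL_MEASURES[:cfg.n_clinical]
    centered = levels - levels.mean(axis=0)
    for k, measure in enumerate(measures):
        chosen = rng.choice(planted_ids, size=min(2, len(planted_ids)), replace=False)
        coefs = rng.choice([-1.0, 1.0], len(chosen))
        for fid, b in zip(chosen, coefs):
            coef_rows.append(dict(measure=measure, feature_id=fid, coefficient=float(b)))
        signal = centered[chosen].to_numpy() @ coefs
        noise = rng.normal(0.0, cfg.clinical_noise_sd, len(levels))
        vals = signal + intercepts.loc[levels.index.get_level_values(0)].to_numpy() + noise
        for (subj, tp), v in zip(levels.index, vals):
            data_rows.append(dict(subject_id=subj, timepoint_months=tp,
                                  measure=measure, value=float(v)))
    truth.clinical_coefs = pd.DataFrame(coef_rows)
    clin = pd.DataFrame(data_rows).pivot_table(index=["subject_id", "timepoint_months"],
                                               columns="measure", values="value").reset_index()
    clin.columns.name = None
    return clin


# ---------------------------------------------------------------------------
# disk convenience (used by the CLI `simulate` stage)
# ---------------------------------------------------------------------------

def simulate_to_dir(cfg: SynthConfig, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t1, t2, meta, truth = generate_cohorts(cfg)
    prov = {"seed": cfg.seed}
    write_feature_table(t1, out / "cohort1_features.tsv", prov)
    write_feature_table(t2, out / "cohort2_features.tsv", prov)
    fu, fu_meta = generate_longitudinal(truth, cfg, meta, features=t1.features)
    write_feature_table(fu, out / "followup_features.tsv", prov)
    all_meta = InjectionMeta(pd.concat([meta.df, fu_meta.df]))
    write_injection_meta(all_meta, out / "injections.tsv", prov)
    clinical = generate_clinical(truth, cfg)
    clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    truth.save(out / "truth")
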