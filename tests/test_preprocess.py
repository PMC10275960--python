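"""Per-cohort filters and run-order drift correction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from csfmet.io import FeatureTable
from csfmet.preprocess import (filter_by_dilution, log2_transform,
                               loess_runorder_normalize, preprocess_cohort,
                               qc_cv_filter, remove_blank_contaminants, tic_report)

from conftest import make_meta


def _table(values: np.ndarray, injections: list[str], scale="raw") -> FeatureTable:
    n = values.shape[0]
    feats = pd.DataFrame({"mz": 100.0 + np.arange(n), "rt": 60.0 + np.arange(n),
                          "ion_mode": "positive"},
                         index=pd.Index([f"f{i}" for i in range(n)], name="feature_id"))
    vals = pd.DataFrame(values, index=feats.index, columns=injections)
    return FeatureTable(feats, vals, scale)


def _qc_blank_meta(n_qc=3, n_blank=2):
    rows = [{"injection_id": f"q{i}", "cohort": 1, "sample_type": "qc",
             "injection_order": i + 1} for i in range(n_qc)]
    rows += [{"injection_id": f"b{i}", "cohort": 1, "sample_type": "blank",
              "injection_order": n_qc + i + 1} for i in range(n_blank)]
    return make_meta(rows)


class TestBlankFilter:
    meta = _qc_blank_meta()

    def test_rule_boundaries(self):
        # rows: equal to blank (removed), exactly 10x (kept), absent in blanks (kept)
        vals = np.array([
            [100.0, 100, 100, 100, 100],
            [1000.0, 1000, 1000, 100, 100],
            [500.0, 500, 500, np.nan, np.nan],
        ])
        t = _table(vals, ["q0", "q1", "q2", "b0", "b1"])
        out, rep = remove_blank_contaminants(t, self.meta, ratio_min=10)
        assert rep.removed == ["f0"]
        assert set(out.feature_ids) == {"f1", "f2"}

    def test_requires_qc(self):
        t = _table(np.ones((1, 2)), ["b0", "b1"])
        meta = make_meta([{"injection_id": f"b{i}", "cohort": 1, "sample_type": "blank",
                           "injection_order": i + 1} for i in range(2)])
        with pytest.raises(ValueError, match="QC"):
            remove_blank_contaminants(t, meta)


class TestDilutionFilter:
    vols = [0.5, 1, 2, 4, 8, 16, 32]
    meta = make_meta([{"injection_id": f"d{i}", "cohort": 1, "sample_type": "dilution",
                       "injection_order": i + 1, "dilution_volume": v}
                      for i, v in enumerate(vols)])

    def test_proportional_kept_constant_removed(self):
        vals = np.vstack([np.array(self.vols) * 3.0, np.full(7, 5.0)])
        t = _table(vals, [f"d{i}" for i in range(7)])
        out, rep = filter_by_dilution(t, self.meta)
        assert out.feature_ids == ["f0"]
        assert rep.removed == ["f1"]

    def test_decision_matches_t_distribution_critical_value(self):
        """With N=6 points, keep iff r exceeds the two-sided 5% critical
        value r* = t / sqrt(t^2 + 4), t = t_{0.975,4} (~0.811)."""
        vols6 = [1, 2, 4, 8, 16, 32.0]
        meta6 = make_meta([{"injection_id": f"d{i}", "cohort": 1,
                            "sample_type": "dilution", "injection_order": i + 1,
                            "dilution_volume": v} for i, v in enumerate(vols6)])
        t_crit = stats.t.ppf(0.975, 4)
        r_crit = t_crit / np.sqrt(t_crit ** 2 + 4)
        rng = np.random.default_rng(0)
        vals = np.abs(rng.normal(100, 50, (200, 6))) + 1
        t = _table(vals, [f"d{i}" for i in range(6)])
        out, rep = filter_by_dilution(t, meta6)
        kept = set(out.feature_ids)
        for i in range(200):
            r = stats.pearsonr(vals[i], vols6)[0]
            assert (f"f{i}" in kept) == (r > r_crit + 1e-12)

    def test_needs_three_volumes(self):
        meta2 = make_meta([{"injection_id": f"d{i}", "cohort": 1,
                            "sample_type": "dilution", "injection_order": i + 1,
                            "dilution_volume": v} for i, v in enumerate([1.0, 2.0])])
        t = _table(np.ones((1, 2)), ["d0", "d1"])
        with pytest.raises(ValueError, match="dilution"):
            filter_by_dilution(t, meta2)


class TestLog2:
    def test_values_and_round_trip(self):
        t = _table(np.array([[8.0, 1.0, np.nan]]), ["a", "b", "c"])
        out = log2_transform(t)
        assert out.scale == "log2"
        assert out.values.iloc[0, 0] == 3.0
        assert out.values.iloc[0, 1] == 0.0
        assert np.isnan(out.values.iloc[0, 2])
        back = np.exp2(out.values.to_numpy())
        np.testing.assert_allclose(back[:, :2], [[8.0, 1.0]], rtol=1e-12)

    def test_nonpositive_entry_named(self):
        t = _table(np.array([[4.0, 0.0]]), ["a", "b"])
        with pytest.raises(ValueError, match="f0.*b"):
            log2_transform(t)


def _runorder_meta(n_inj, qc_every=5):
    rows = []
    for i in range(n_inj):
        kind = "qc" if i % qc_every == 0 else "study"
        row = {"injection_id": f"i{i}", "cohort": 1, "sample_type": kind,
               "injection_order": i + 1}
        if kind == "study":
            row.update(subject_id=f"s{i}", group="RRMS", age=40.0, sex="F")
        rows.append(row)
    return make_meta(rows)


class TestLoess:
    def test_linear_drift_removed_exactly(self):
        n = 60
        meta = _runorder_meta(n)
        order = np.arange(1, n + 1, dtype=float)
        vals = (20.0 + 0.05 * order)[None, :]
        t = _table(vals, [f"i{i}" for i in range(n)], scale="log2")
        out, _ = loess_runorder_normalize(t, meta, span=0.2)
        qc_ids = [f"i{i}" for i in range(0, n, 5)]
        qc_vals = out.values[qc_ids].to_numpy()[0]
        qc_mean_before = vals[0, [i for i in range(0, n, 5)]].mean()
        np.testing.assert_allclose(qc_vals, qc_mean_before, atol=1e-6)
        # all (linearly drifting) injections are flattened too
        np.testing.assert_allclose(out.values.to_numpy()[0], qc_mean_before, atol=1e-6)

    def test_no_drift_is_identity(self):
        n = 40
        meta = _runorder_meta(n)
        rng = np.random.default_rng(1)
        vals = np.full((3, n), 18.0)
        vals[:, [i for i in range(n) if i % 5 != 0]] += rng.normal(0, 1, (3, n - len(range(0, n, 5))))
        t = _table(vals, [f"i{i}" for i in range(n)], scale="log2")
        out, _ = loess_runorder_normalize(t, meta, span=0.2)
        np.testing.assert_allclose(out.values.to_numpy(), vals, atol=1e-9)

    def test_sinusoidal_drift_suppressed(self):
        """Injected sinusoid (amplitude 1.0 log2, noise 0.1): QC standard
        deviation drops by at least 80% after normalization."""
        n = 200
        meta = _runorder_meta(n, qc_every=7)
        order = np.arange(1, n + 1, dtype=float)
        rng = np.random.default_rng(2)
        drift = 1.0 * np.sin(2 * np.pi * order / n)
        vals = 20.0 + drift + rng.normal(0, 0.1, n)
        t = _table(vals[None, :], [f"i{i}" for i in range(n)], scale="log2")
        out, _ = loess_runorder_normalize(t, meta, span=0.2)
        qc_idx = [i for i in range(0, n, 7)]
        before = np.std(vals[qc_idx])
        after = np.std(out.values.to_numpy()[0, qc_idx])
        assert after <= 0.2 * before

    def test_idempotent(self):
        n = 100
        meta = _runorder_meta(n, qc_every=6)
        order = np.arange(1, n + 1, dtype=float)
        rng = np.random.default_rng(3)
        vals = 20.0 + 0.5 * np.sin(2 * np.pi * order / 60) + rng.normal(0, 0.1, n)
        t = _table(vals[None, :], [f"i{i}" for i in range(n)], scale="log2")
        once, _ = loess_runorder_normalize(t, meta, span=0.2)
        twice, _ = loess_runorder_normalize(once, meta, span=0.2)
        np.testing.assert_allclose(twice.values.to_numpy(), once.values.to_numpy(),
                                   atol=1e-6)

    def test_missing_entries_untouched(self):
        n = 30
        meta = _runorder_meta(n)
        vals = np.full((1, n), 20.0)
        vals[0, 3] = np.nan
        t = _table(vals, [f"i{i}" for i in range(n)], scale="log2")
        out, _ = loess_runorder_normalize(t, meta)
        assert np.isnan(out.values.iloc[0, 3])


class TestCvFilter:
    def _qc_table(self, delogged_rows):
        log2 = np.log2(np.asarray(delogged_rows, float))
        return _table(log2, [f"q{i}" for i in range(log2.shape[1])], scale="log2")

    meta = make_meta([{"injection_id": f"q{i}", "cohort": 1, "sample_type": "qc",
                       "injection_order": i + 1} for i in range(3)])

    def test_cv_rule_with_strict_boundary(self):
        t = self._qc_table([[90, 100, 110],    # CV = 0.10 -> kept
                            [50, 100, 150],    # CV = 0.50 -> removed
                            [80, 100, 120]])   # CV = 0.20 -> removed (strict <)
        out, rep = qc_cv_filter(t, self.meta, cv_max=0.20)
        assert out.feature_ids == ["f0"]
        assert set(rep.removed) == {"f1", "f2"}

    def test_all_missing_qc_removed_and_flagged(self):
        t = self._qc_table([[90, 100, 110]])
        t.values.iloc[0, :] = np.nan
        out, rep = qc_cv_filter(t, self.meta)
        assert out.shape[0] == 0 and rep.flagged == ["f0"]


class TestTicReport:
    def test_identical_injections_unflagged(self):
        t = _table(np.ones((3, 10)), [f"i{k}" for k in range(10)])
        rep = tic_report(t, None)
        assert rep.flagged == []

    def test_extreme_injection_flagged(self):
        rng = np.random.default_rng(0)
        vals = 1.0 + rng.uniform(0, 0.05, (2, 20))
        vals[:, 5] = 100.0
        t = _table(vals, [f"i{k}" for k in range(20)])
        rep = tic_report(t, None)
        assert rep.flagged == ["i5"]

    def test_tic_is_sum_of_present_intensities(self):
        t = _table(np.array([[3.0], [5.0]]), ["i0"])
        rep = tic_report(t, None)
        assert rep.details.loc["i0", "tic"] == 8.0


def test_full_pipeline_removes_contaminants_keeps_real_features(small_synth):
    """On synthetic data every planted contaminant falls to the blank filter
    and almost no genuine feature is lost to it."""
    _, t1, _, meta, truth = small_synth
    out, reports = preprocess_cohort(t1, meta)
    blank_removed = set(next(r for r in reports if r.stage == "blank_filter").removed)
    contams = set(truth.contaminants[1])
    assert contams <= blank_removed
    false_removals = blank_removed - contams
    assert len(false_removals) / (t1.shape[0] - len(contams)) < 0.05
    assert set(out.feature_ids) <= set(t1.feature_ids)
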