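import numpy as np
import pandas as pd
import pytest

from lipidflow import preprocess as pre
from lipidflow import simulate as sim
from conftest import make_feature_table


class TestDriftCorrect:
    def test_closed_form_worked_example(self):
        """QC areas 100/120/140 at orders 1/5/9: the fitted line is
        95 + 5*order, the reference fit at the median QC order is 120, and
        the value at order 9 corrects from 140 to 140/(140/120) = 120."""
        areas = np.array([[150.0]])
        qc = np.array([[100.0, 120.0, 140.0]])
        table, _ = make_feature_table(areas, qc=qc)
        # orders: qc at 1,2,3 then study at 4 -> rebuild with explicit orders
        table.injections["order"] = [1, 5, 9, 10]
        out, rep = pre.drift_correct(table)
        assert rep.loc["F0", "corrected"]
        # the QC injection at order 9 evaluates the fit at 9 exactly
        assert out.areas.loc["F0", "qc2"] == pytest.approx(120.0)
        # study injection at order 10: fit(10) = 145
        assert out.areas.loc["F0", "inj_s0"] == pytest.approx(150 * 120 / 145)

    def test_zero_slope_identity(self):
        table, _ = make_feature_table([[80.0, 90.0]], qc=[[100, 100, 100]])
        out, rep = pre.drift_correct(table)
        assert np.allclose(out.areas.to_numpy(), table.areas.to_numpy())

    def test_too_few_qcs_flagged_unchanged(self):
        table, _ = make_feature_table([[80.0]], qc=[[100, 110, np.nan]])
        out, rep = pre.drift_correct(table)
        assert not rep.loc["F0", "corrected"]
        assert rep.loc["F0", "reason"] == "insufficient_qc"
        assert out.areas.loc["F0", "inj_s0"] == 80.0

    def test_nonpositive_fit_skipped(self):
        # steep negative slope drives the fitted line below zero downstream
        table, _ = make_feature_table([[5.0]], qc=[[300, 150, 10]])
        table.injections["order"] = [1, 2, 3, 50]
        out, rep = pre.drift_correct(table)
        assert rep.loc["F0", "reason"] == "nonpositive_fit"
        assert out.areas.loc["F0", "inj_s0"] == 5.0

    def test_reduces_qc_cv_on_simulated_drift(self):
        study = sim.simulate_study(sim.StudyDesign(tissues=("LIVER",), seed=2),
                                   effects=[], drift_sd=0.15, seed=2)
        t = study.untargeted[("LIVER", "positive")]
        out, _ = pre.drift_correct(t)
        def cv(tab):
            qc = tab.qc_areas
            return (qc.std(axis=1, ddof=1) / qc.mean(axis=1)).dropna()
        before, after = cv(t), cv(out)
        assert after.median() <= before.median()


class TestQcFilter:
    def test_rules_fire_exactly(self):
        areas = np.array([
            [100, 100, 100],    # clean
            [40, 40, 40],       # blank rule: blank bg 10 -> 40 < 50
            [100, 100, 100],    # presence rule (QCs missing)
            [100, 100, 100],    # CV rule
        ], dtype=float)
        qc = np.array([
            [100, 100, 100, np.nan],
            [100, 100, 100, 100],
            [100, np.nan, np.nan, np.nan],
            [50, 150, 50, 150],
        ])
        blank = np.array([[1.0], [10.0], [1.0], [1.0]])
        table, _ = make_feature_table(areas, qc=qc, blank=blank)
        out, log = pre.qc_filter(table)
        assert list(out.areas.index) == ["F0"]
        rules = dict(zip(log["feature_id"], log["rules"]))
        assert rules["F1"] == "blank_ratio"
        assert rules["F2"] == "qc_presence"
        assert rules["F3"] == "qc_cv"

    def test_qc_cv_arithmetic(self):
        # QC areas {50,150}: CV = sd/mean = 70.71/100 > 30%
        table, _ = make_feature_table([[100.0]], qc=[[50.0, 150.0]],
                                      blank=[[0.0]])
        out, log = pre.qc_filter(table)
        assert len(out.areas) == 0
        assert log["rules"].iloc[0] == "qc_cv"

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        areas = rng.uniform(50, 150, (20, 6))
        qc = rng.uniform(90, 110, (20, 4))
        blank = rng.uniform(0, 30, (20, 2))
        table, _ = make_feature_table(areas, qc=qc, blank=blank)
        once, _ = pre.qc_filter(table)
        twice, log2 = pre.qc_filter(once)
        assert list(once.areas.index) == list(twice.areas.index)
        assert len(log2) == 0


class TestRemoveDegenerate:
    def _tables(self, cv_pos, cv_neg):
        # encode target CVs via two QC injections {m(1-c), m(1+c)} -> sd/mean = c*sqrt(2)
        def qc_for(c):
            return [100 * (1 - c / np.sqrt(2)), 100 * (1 + c / np.sqrt(2))]
        pos, _ = make_feature_table([[100.0]], qc=[qc_for(cv_pos)],
                                    names=["PC 34:1"], esi_mode="positive")
        neg, _ = make_feature_table([[100.0]], qc=[qc_for(cv_neg)],
                                    names=["PC 34:1"], esi_mode="negative")
        return pos, neg

    def test_lower_cv_kept(self):
        pos, neg = self._tables(0.10, 0.20)
        p2, n2, log = pre.remove_degenerate(pos, neg)
        assert len(p2.areas) == 1 and len(n2.areas) == 0
        assert log["kept_mode"].iloc[0] == "positive"
        p3, n3 = self._tables(0.20, 0.10)
        p3, n3, log3 = pre.remove_degenerate(p3, n3)
        assert len(p3.areas) == 0 and log3["kept_mode"].iloc[0] == "negative"

    def test_tie_keeps_positive_flagged(self):
        pos, neg = self._tables(0.15, 0.15)
        p2, n2, log = pre.remove_degenerate(pos, neg)
        assert len(p2.areas) == 1 and len(n2.areas) == 0
        assert log["tie"].iloc[0]

    def test_unique_names_untouched(self):
        pos, _ = make_feature_table([[100.0]], qc=[[100, 100]],
                                    names=["PC 34:1"])
        neg, _ = make_feature_table([[100.0]], qc=[[100, 100]],
                                    names=["PE 34:1"], esi_mode="negative")
        p2, n2, log = pre.remove_degenerate(pos, neg)
        assert len(p2.areas) == 1 and len(n2.areas) == 1 and len(log) == 0


class TestNormalize:
    def test_feature_and_sample_medians(self):
        rng = np.random.default_rng(1)
        areas = rng.lognormal(10, 1, (30, 9))
        table, _ = make_feature_table(areas)
        norm = pre.normalize(table)
        # feature medians exactly 0 before centering: reconstruct by adding
        # the sample medians back
        v = norm.values
        assert np.allclose(v.median(axis=0), 0.0, atol=1e-12)
        logged = np.log2(areas)
        std = ((logged - np.median(logged, 1, keepdims=True))
               / np.std(logged, 1, ddof=1, keepdims=True))
        assert np.allclose(np.median(std, axis=1), 0.0, atol=1e-12)
        recon = std - np.median(std, axis=0, keepdims=True)
        assert np.allclose(v.to_numpy(), recon)

    def test_constant_feature_flagged_zero(self):
        table, _ = make_feature_table(np.full((1, 5), 64.0))
        norm = pre.normalize(table)
        assert "F0" in norm.zero_variance
        # the lone constant feature standardizes to zeros; sample medians are
        # then zero too, so centering leaves it at exactly zero
        assert np.allclose(norm.values.loc["F0"], 0.0, atol=1e-12)

    def test_worked_3x3(self):
        areas = 2.0 ** np.array([[1, 2, 3], [4, 6, 8], [10, 10, 13.0]])
        table, _ = make_feature_table(areas)
        v = pre.normalize(table).values.to_numpy()
        logged = np.log2(areas)
        std = ((logged - np.median(logged, 1, keepdims=True))
               / np.std(logged, 1, ddof=1, keepdims=True))
        expected = std - np.median(std, axis=0, keepdims=True)
        assert np.allclose(v, expected)


class TestOutliers:
    def test_planted_outlier_flagged_clean_not(self, null_study):
        study = sim.simulate_study(
            sim.StudyDesign(tissues=("LIVER",), seed=3), effects=[],
            planted_outliers=1, seed=3)
        t = study.untargeted[("LIVER", "positive")]
        rep = pre.detect_outlier_samples(t)
        planted = study.truth.outlier_samples[("LIVER", "positive")]
        assert set(rep.flagged) == set(planted)
        clean = pre.detect_outlier_samples(
            null_study.untargeted[("LIVER", "positive")])
        assert clean.flagged == []

    def test_duplicate_sample_not_flagged(self):
        # shared per-feature abundance spread drives raw-scale correlations,
        # as in real feature tables
        rng = np.random.default_rng(4)
        base = rng.uniform(8, 20, 40)
        areas = 2.0 ** (base[:, None] + rng.normal(0, 0.3, (40, 6)))
        areas[:, 5] = areas[:, 4]
        table, _ = make_feature_table(areas)
        rep = pre.detect_outlier_samples(table)
        assert "s5" not in rep.flagged
        assert rep.median_correlation["s5"] > 0.75
        # correlation to its twin is exactly 1
        assert table.study_areas.corr().loc["s5", "s4"] == pytest.approx(1.0)


class TestCrossTissuePca:
    def _mats(self, rng, shift_b=0.0):
        lipids = [f"lip{i}" for i in range(30)]
        a = pd.DataFrame(rng.normal(10, 1, (30, 6)), index=lipids)
        b = pd.DataFrame(rng.normal(10 + shift_b, 1, (30, 6)), index=lipids)
        return {"A": a, "B": b}

    def test_representation_filter(self):
        rng = np.random.default_rng(5)
        mats = self._mats(rng)
        mats["A"].iloc[0] = np.nan            # lip0 in only 1 of 2 tissues
        res = pre.cross_tissue_pca(mats, min_tissues=2)
        assert "lip0" not in res.lipids
        with pytest.raises(ValueError):
            pre.cross_tissue_pca(mats, min_tissues=3)

    def test_identical_tissues_no_separation(self):
        rng = np.random.default_rng(6)
        a = pd.DataFrame(rng.normal(10, 1, (30, 6)),
                         index=[f"lip{i}" for i in range(30)])
        res = pre.cross_tissue_pca({"A": a, "B": a.copy()}, min_tissues=2)
        pc1 = res.scores["PC1"]
        assert abs(pc1.loc["A"].mean() - pc1.loc["B"].mean()) < 1e-9

    def test_planted_tissue_shift_separates(self):
        # per-lipid (not uniform) tissue differences: sample median-centering
        # removes a global shift by design
        rng = np.random.default_rng(7)
        mats = self._mats(rng)
        mats["B"] = mats["B"].add(rng.normal(0, 5, 30), axis=0)
        res = pre.cross_tissue_pca(mats, min_tissues=2)
        pc1 = res.scores["PC1"]
        gap = abs(pc1.loc["A"].mean() - pc1.loc["B"].mean())
        spread = pc1.loc["A"].std() + pc1.loc["B"].std()
        assert gap > spread


class TestVarianceComponents:
    def test_pure_between(self):
        y = pd.Series([1, 1, 1, 5, 5, 5.0])
        g = pd.Series(["a"] * 3 + ["b"] * 3)
        assert pre.variance_components(y, g) == pytest.approx(1.0)

    def test_closed_form_two_group(self):
        y = pd.Series([0, 2, 10, 12.0])           # means 1, 11; MSW = 2
        g = pd.Series(["a", "a", "b", "b"])
        msb = 2 * ((1 - 6) ** 2 + (11 - 6) ** 2) / 1
        msw = 2.0
        sb = (msb - msw) / 2
        expected = sb / (sb + msw)
        assert pre.variance_components(y, g) == pytest.approx(expected)

    def test_null_near_zero(self):
        rng = np.random.default_rng(8)
        fracs = []
        for _ in range(50):
            y = pd.Series(rng.normal(size=40))
            g = pd.Series(rng.permutation(["a", "b", "c", "d"] * 10))
            fracs.append(pre.variance_components(y, g))
        assert np.median(fracs) < 0.05

    def test_singleton_group_raises(self):
        with pytest.raises(ValueError):
            pre.variance_components(pd.Series([1, 2, 3.0]),
                                    pd.Series(["a", "a", "b"]))


class TestTargetedQc:
    def test_filters_and_twin_imputation(self):
        rng = np.random.default_rng(9)
        base = rng.uniform(5, 50, (6, 10))
        conc = pd.DataFrame(base, index=[f"a{i}" for i in range(6)])
        conc.iloc[5] = conc.iloc[4]               # identical twin of a4
        conc.iloc[5, 3] = np.nan
        conc.iloc[0, :3] = np.nan                 # 30% missing -> removed
        qc_conc = pd.DataFrame(rng.uniform(95, 105, (6, 5)), index=conc.index)
        qc_conc.iloc[1] = [10, 300, 10, 300, 10]  # CV > 100%
        qc_rt = pd.DataFrame(5.0 + rng.normal(0, 0.01, (6, 5)),
                             index=conc.index)
        qc_rt.iloc[2] = [4, 6, 4, 6, 4]           # RT CV > 10%
        res = pre.targeted_qc(conc, qc_conc, qc_rt, k=1)
        rules = dict(zip(res.removal_log["analyte"], res.removal_log["rule"]))
        assert rules == {"a1": "conc_cv", "a2": "rt_cv", "a0": "missingness"}
        assert set(res.concentrations.index) == {"a3", "a4", "a5"}
        # k=1 with an identical twin copies the twin's value exactly
        assert res.concentrations.loc["a5", 3] == pytest.approx(
            conc.loc["a4", 3])
        assert res.imputed.loc["a5", 3]

    def test_mean_fallback_when_too_few_neighbors(self):
        conc = pd.DataFrame([[1.0, 2, 3, 4, np.nan], [10, 20, 30, 40, 50]],
                            index=["a", "b"])
        res = pre.targeted_qc(conc, k=5)
        assert "a" in res.mean_fallback
        assert res.concentrations.loc["a", 4] == pytest.approx(2.5)
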