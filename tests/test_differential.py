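import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidflow import differential as diff
from lipidflow import simulate as sim


def _two_group(seed=0, G=60, n=5, delta=0.0):
    rng = np.random.default_rng(seed)
    meta = pd.DataFrame({"group": ["SED"] * n + ["1w"] * n},
                        index=[f"s{i}" for i in range(2 * n)])
    Y = rng.normal(size=(G, 2 * n))
    Y[: G // 4, n:] += delta
    return pd.DataFrame(Y, columns=meta.index), meta


class TestDesigns:
    def test_means_coding_coefficients_are_cell_means(self):
        Y, meta = _two_group(1)
        m = diff.ModeratedLinearModel.from_dataframe(Y, meta, coding="means")
        res = m.fit(moderate=False)
        assert np.allclose(res.coef["SED"], Y.iloc[:, :5].mean(axis=1))
        assert np.allclose(res.coef["1w"], Y.iloc[:, 5:].mean(axis=1))

    def test_mean_reference_coding(self):
        Y, meta = _two_group(2)
        m = diff.ModeratedLinearModel.from_dataframe(Y, meta,
                                                     coding="mean_reference")
        res = m.fit(moderate=False)
        assert list(res.coef.columns) == ["Intercept", "1w"]
        assert np.allclose(res.coef["Intercept"], Y.iloc[:, :5].mean(axis=1))

    def test_rank_deficiency_names_aliased(self):
        X = pd.DataFrame({"a": [1, 1, 1, 1], "b": [1, 0, 1, 0],
                          "c": [1, 0, 1, 0.0]})
        Y = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 4)))
        with pytest.raises(ValueError, match="c"):
            diff.ModeratedLinearModel(Y, X)

    def test_zero_noise_fixture(self):
        meta = pd.DataFrame({"group": ["SED"] * 5 + ["1w"] * 5},
                            index=[f"s{i}" for i in range(10)])
        Y = pd.DataFrame([[1.0] * 5 + [3.0] * 5], columns=meta.index)
        res = diff.ModeratedLinearModel.from_dataframe(
            Y, meta, coding="means").fit(moderate=False)
        assert res.s2.iloc[0] == pytest.approx(0.0)
        assert res.df_resid == 8

    def test_ols_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        meta = pd.DataFrame({"group": rng.choice(["a", "b", "c"], 15)},
                            index=[f"s{i}" for i in range(15)])
        Y = pd.DataFrame(rng.normal(size=(10, 15)), columns=meta.index)
        m = diff.ModeratedLinearModel.from_dataframe(Y, meta, coding="means")
        res = m.fit(moderate=False)
        X = m.design.to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ Y.to_numpy().T).T
        assert np.allclose(res.coef.to_numpy(), beta)


class TestPrior:
    def test_recovery_from_scaled_chisquare(self):
        """Variances drawn from the scaled chi-square hierarchy (d0=4,
        s0^2=0.25, df=8) are recovered within 15% / 10% (median over 10
        seeds)."""
        d0s, s02s = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            sg2 = 0.25 * 4.0 / rng.chisquare(4.0, 2000)
            s2 = sg2 * rng.chisquare(8, 2000) / 8
            prior = diff.estimate_prior(s2, 8)
            d0s.append(prior.d0)
            s02s.append(prior.s02)
        assert abs(np.median(d0s) - 4.0) / 4.0 < 0.15
        assert abs(np.median(s02s) - 0.25) / 0.25 < 0.10

    def test_identical_variances_degenerate(self):
        prior = diff.estimate_prior(np.full(50, 0.7), 8)
        assert np.isinf(prior.d0)
        assert prior.s02 == pytest.approx(0.7, rel=0.25)

    def test_heterogeneous_variances_small_d0(self):
        rng = np.random.default_rng(1)
        sg2 = 0.25 * 0.5 / rng.chisquare(0.5, 3000)   # true d0 = 0.5
        s2 = sg2 * rng.chisquare(8, 3000) / 8
        prior = diff.estimate_prior(s2, 8)
        assert prior.d0 < 8

    def test_too_few_lipids(self):
        with pytest.raises(ValueError):
            diff.estimate_prior(np.ones(5), 8)


class TestModeratedT:
    def test_d0_zero_equals_classical_t(self):
        Y, meta = _two_group(4)
        m = diff.ModeratedLinearModel.from_dataframe(Y, meta, coding="means")
        res = m.fit(moderate=False)
        tab = res.contrast({"1w": 1.0, "SED": -1.0})
        classical = np.array([
            stats.ttest_ind(Y.iloc[i, 5:], Y.iloc[i, :5]).statistic
            for i in range(len(Y))])
        assert np.max(np.abs(tab["t"].to_numpy() - classical)) < 1e-10

    def test_infinite_d0_uses_prior_variance(self):
        Y, meta = _two_group(5)
        m = diff.ModeratedLinearModel.from_dataframe(Y, meta, coding="means")
        prior = diff.ModerationPrior(d0=np.inf, s02=1.0)
        res = m.fit(prior=prior)
        tab = res.contrast({"1w": 1.0, "SED": -1.0})
        lfc = tab["logFC"].to_numpy()
        expected = lfc / np.sqrt(1.0 * 2 / 5)
        assert np.allclose(tab["t"], expected)
        # p-values come from the normal limit
        assert np.allclose(tab["p"], 2 * stats.norm.sf(np.abs(expected)))

    def test_posterior_variance_formula(self):
        Y, meta = _two_group(6)
        m = diff.ModeratedLinearModel.from_dataframe(Y, meta, coding="means")
        prior = diff.ModerationPrior(d0=4.0, s02=0.5)
        res = m.fit(prior=prior)
        tab = res.contrast({"1w": 1.0, "SED": -1.0})
        s2p = (4.0 * 0.5 + 8 * res.s2.to_numpy()) / 12.0
        expected = tab["logFC"].to_numpy() / np.sqrt(s2p * 2 / 5)
        assert np.allclose(tab["t"], expected)
        assert np.allclose(tab["p"],
                           2 * stats.t.sf(np.abs(expected), 12.0))

    def test_logfc_is_difference_of_cell_means(self):
        Y, meta = _two_group(7, delta=1.0)
        m = diff.ModeratedLinearModel.from_dataframe(Y, meta, coding="means")
        tab = m.fit().contrast({"1w": 1.0, "SED": -1.0})
        expected = Y.iloc[:, 5:].mean(axis=1) - Y.iloc[:, :5].mean(axis=1)
        assert np.allclose(tab["logFC"], expected)


class TestModeratedF:
    def _fit(self, seed=8):
        rng = np.random.default_rng(seed)
        meta = pd.DataFrame(
            {"group": sum(([g] * 5 for g in ("SED", "1w", "2w")), [])},
            index=[f"s{i}" for i in range(15)])
        Y = pd.DataFrame(rng.normal(size=(40, 15)), columns=meta.index)
        return diff.ModeratedLinearModel.from_dataframe(
            Y, meta, coding="means").fit()

    def test_single_contrast_equals_t_squared(self):
        res = self._fit()
        c = {"1w": 1.0, "SED": -1.0}
        f = res.f_test([c])
        t = res.contrast(c)
        assert np.allclose(f["F"], t["t"] ** 2)
        assert np.allclose(f["p"], t["p"])

    def test_dependent_contrasts_raise(self):
        res = self._fit()
        with pytest.raises(ValueError):
            res.f_test([{"1w": 1.0, "SED": -1.0}, {"1w": 2.0, "SED": -2.0}])

    def test_null_f_p_uniform(self):
        res = self._fit(seed=9)
        f = res.f_test([{"1w": 1, "SED": -1}, {"2w": 1, "SED": -1}])
        ks = stats.kstest(f["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_f_tracks_the_strong_timepoint(self):
        rng = np.random.default_rng(10)
        meta = pd.DataFrame(
            {"group": sum(([g] * 5 for g in ("SED", "1w", "2w", "4w", "8w")), [])},
            index=[f"s{i}" for i in range(25)])
        Y = rng.normal(size=(50, 25))
        Y[:10, 10:15] += 2.5      # strong 2w effect in first 10 lipids
        Y = pd.DataFrame(Y, columns=meta.index)
        res = diff.ModeratedLinearModel.from_dataframe(
            Y, meta, coding="means").fit()
        f = res.f_test([{tp: 1, "SED": -1} for tp in ("1w", "2w", "4w", "8w")])
        assert (f["adj_p"].iloc[:10] < 0.05).mean() >= 0.9
        assert (f["adj_p"].iloc[10:] < 0.05).mean() <= 0.1


class TestSexContrasts:
    def _matrix(self, male_8w=0.0, shared=0.0, seed=11):
        rng = np.random.default_rng(seed)
        rows = []
        for sex in ("male", "female"):
            for g in ("SED", "1w", "2w", "4w", "8w"):
                for i in range(5):
                    rows.append({"sex": sex, "group": g})
        meta = pd.DataFrame(rows, index=[f"s{i}" for i in range(50)])
        Y = rng.normal(size=(30, 50), scale=0.5)
        trained = [i for i, r in enumerate(meta.itertuples())
                   if r.group != "SED"]
        male8 = [i for i, r in enumerate(meta.itertuples())
                 if r.sex == "male" and r.group == "8w"]
        Y[:, trained] += shared
        Y[:10, male8] += male_8w
        return pd.DataFrame(Y, columns=meta.index), meta

    def test_shared_response_cancels_in_interaction(self):
        Y, meta = self._matrix(shared=2.0)
        out = diff.sex_contrast_results(Y, meta)
        inter = out[out["family"] == "interaction"]
        assert (inter["adj_p"] < 0.05).mean() < 0.05

    def test_male_only_effect_appears_at_8w(self):
        Y, meta = self._matrix(male_8w=3.0)
        out = diff.sex_contrast_results(Y, meta)
        i8 = out[(out["family"] == "interaction") & (out["timepoint"] == "8w")]
        i8 = i8.set_index("lipid").loc[[i for i in range(10)]]
        # logFC estimates the planted delta (sampling sd ~ 0.45 per lipid)
        assert i8["logFC"].mean() == pytest.approx(3.0, abs=0.5)
        assert np.allclose(i8["logFC"], 3.0, atol=1.6)
        assert (i8["adj_p"] < 0.05).all()

    def test_interaction_signs_match_truth(self):
        """A planted male-only (sex-dimorphic) response: interaction logFC
        signs agree with the generator's truth end to end."""
        from lipidflow.pipeline import _preprocess_tissue
        effects = [sim.EffectSpec({"lipid_class": "Car"}, "sex_by_time",
                                  sizes={"1w": 2.0, "2w": 3.0, "4w": 3.0,
                                         "8w": 3.0},
                                  sexes=("male",), label="male_car")]
        study = sim.simulate_study(
            sim.StudyDesign(tissues=("LIVER",), seed=31), effects=effects,
            seed=31)
        _, combined, _ = _preprocess_tissue(study, "LIVER")
        meta = study.samples[study.samples["tissue"] == "LIVER"]
        out = diff.sex_contrast_results(combined.values, meta)
        pt = study.truth.planted_timewise
        male_only = pt[pt["effect"].abs() >= 1.0]
        merged = out[out["family"] == "interaction"].merge(
            male_only, on=["lipid", "timepoint"])
        assert len(merged) > 20
        concordance = (np.sign(merged["logFC"])
                       == np.sign(merged["effect"])).mean()
        assert concordance > 0.9

    def test_missing_cell_skipped(self):
        Y, meta = self._matrix()
        drop = meta.index[(meta["sex"] == "female") & (meta["group"] == "8w")]
        Y2 = Y.drop(columns=drop)
        out = diff.sex_contrast_results(Y2, meta.drop(index=drop))
        assert "naive_8w" in out.attrs["skipped"]
        assert "interaction_8w" in out.attrs["skipped"]


class TestBH:
    def test_bh_formula(self):
        adj = diff.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert diff.bh_adjust([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(diff.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_and_geq_raw(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=200)
        adj = diff.bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestCalibration:
    def test_null_type_i_error(self):
        """Raw p < 0.05 fraction within 0.05 +/- 0.01 on a 2000-lipid null."""
        M, meta, _ = sim.simulate_normalized_matrix(2000, seed=21)
        tw = diff.timewise_results(M, meta)
        frac = (tw["p"] < 0.05).mean()
        assert 0.04 <= frac <= 0.06

    def test_planted_recovery(self):
        """Standardized effect 3.0 at n=5: sensitivity >= 0.8 and empirical
        FDR <= 0.10 at 5% BH (median over seeds)."""
        sens, fdrs = [], []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            planted = rng.choice(2000, 40, replace=False)
            effects = {f"L{i:04d}": {tp: (3.0 if j < 20 else -3.0)
                                     for tp in ("1w", "2w", "4w", "8w")}
                       for j, i in enumerate(planted)}
            M, meta, pl = sim.simulate_normalized_matrix(
                2000, effects=effects, seed=seed)
            tw = diff.timewise_results(M, meta)
            truth = set(map(tuple, pl[["lipid", "timepoint"]].to_numpy()))
            disc = tw[tw["adj_p"] < 0.05]
            found = set(map(tuple, disc[["lipid", "timepoint"]].to_numpy()))
            sens.append(len(found & truth) / len(truth))
            fdrs.append(len(found - truth) / max(len(found), 1))
        assert np.median(sens) >= 0.8
        assert np.median(fdrs) <= 0.10


@pytest.mark.timeout(300)
def test_matches_limma_oracle(tmp_path):
    """Moderated statistics agree with the reference empirical-Bayes
    implementation (limma, run through Rscript) on a shared fixture."""
    rng = np.random.default_rng(42)
    G, n = 80, 5
    meta = pd.DataFrame({"group": ["SED"] * n + ["1w"] * n},
                        index=[f"s{i}" for i in range(2 * n)])
    Y = pd.DataFrame(rng.normal(size=(G, 2 * n)) * rng.uniform(0.5, 2, (G, 1)),
                     index=[f"L{i}" for i in range(G)], columns=meta.index)
    Y.iloc[:10, n:] += 1.5
    csv = tmp_path / "y.csv"
    Y.to_csv(csv)
    rscript = tmp_path / "run.R"
    rscript.write_text(textwrap.dedent(f"""
        suppressMessages(library(limma))
        y <- as.matrix(read.csv("{csv}", row.names=1, check.names=FALSE))
        tr <- factor(c(rep("SED", {n}), rep("w1", {n})), levels=c("SED","w1"))
        X <- model.matrix(~0+tr)
        colnames(X) <- levels(tr)
        fit <- lmFit(y, X)
        fit2 <- contrasts.fit(fit, makeContrasts(w1-SED, levels=X))
        fit2 <- eBayes(fit2)
        out <- data.frame(t=fit2$t[,1], p=fit2$p.value[,1],
                          d0=fit2$df.prior, s02=fit2$s2.prior)
        write.csv(out, "{tmp_path}/limma.csv")
    """))
    proc = subprocess.run(["Rscript", str(rscript)], capture_output=True,
                          text=True)
    assert proc.returncode == 0, proc.stderr
    ref = pd.read_csv(tmp_path / "limma.csv", index_col=0)

    res = diff.ModeratedLinearModel.from_dataframe(
        Y, meta, coding="means").fit()
    tab = res.contrast({"1w": 1.0, "SED": -1.0})
    assert res.prior.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
    assert res.prior.s02 == pytest.approx(ref["s02"].iloc[0], rel=1e-4)
    assert np.allclose(tab["t"].to_numpy(), ref["t"].to_numpy(), atol=1e-6)
    assert np.allclose(tab["p"].to_numpy(), ref["p"].to_numpy(), atol=1e-8)
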