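import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from lipidflow import network as net
from lipidflow import simulate as sim


class TestCorrelationNetwork:
    def test_duplicated_lipid_across_tissues(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame(rng.normal(size=(5, 10)), columns=range(10))
        mats = {"A": a, "B": a.copy()}
        g = net.build_correlation_network(mats)
        dup = g.edges[(g.edges["scope"] == "inter")
                      & (g.edges["r"] > 0.999999)]
        assert len(dup) >= 5
        assert g.summary().startswith("NetworkGraph")

    def test_null_false_edges_below_bound(self):
        """Bonferroni-corrected null networks: mean false-edge count < 1
        over 20 seeds."""
        counts = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mats = {"A": pd.DataFrame(rng.normal(size=(50, 10)),
                                      columns=range(10)),
                    "B": pd.DataFrame(rng.normal(size=(50, 10)),
                                      columns=range(10))}
            counts.append(len(net.build_correlation_network(mats).edges))
        assert np.mean(counts) < 1.0

    def test_planted_cross_tissue_block_dominates(self):
        """A liver-plasma co-varying block yields the most inter-tissue
        edges for that pair."""
        rng = np.random.default_rng(1)
        n = 12
        z = rng.normal(size=n)
        mats = {}
        for tissue in ("LIVER", "PLASMA", "LUNG"):
            X = rng.normal(0, 1, (40, n))
            if tissue in ("LIVER", "PLASMA"):
                X[:15] = 2.0 * z + rng.normal(0, 0.4, (15, n))
            mats[tissue] = pd.DataFrame(X, columns=range(n))
        g = net.build_correlation_network(mats)
        counts = g.tissue_pair_counts()
        inter = counts[counts["tissue_pair"].map(lambda p: p[0] != p[1])]
        by_pair = inter.groupby("tissue_pair")["n_edges"].sum()
        assert by_pair.idxmax() == ("LIVER", "PLASMA")

    def test_edges_symmetric_no_self_loops(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=8)
        mats = {"A": pd.DataFrame(z + rng.normal(0, 0.2, (20, 8)),
                                  columns=range(8))}
        g = net.build_correlation_network(mats)
        assert (g.edges["node_a"] != g.edges["node_b"]).all()
        pairs = set(map(tuple, g.edges[["node_a", "node_b"]].to_numpy()))
        assert all((b, a) not in pairs for a, b in pairs)
        assert (g.edges["adj_p"] < g.alpha).all()

    def test_too_few_matched_animals(self):
        mats = {"A": pd.DataFrame(np.ones((3, 2)), columns=[0, 1])}
        with pytest.raises(ValueError):
            net.build_correlation_network(mats)


class TestTom:
    def test_perfectly_correlated_profiles_reach_one(self):
        """A rank-one, all-positively-correlated table: every adjacency is
        1 and the topological overlap is exactly 1."""
        rng = np.random.default_rng(3)
        base = rng.normal(size=15)
        scale = rng.uniform(0.5, 2.0, 8)
        X = pd.DataFrame(np.outer(scale, base))
        tom = net.tom_similarity(X, beta=6)
        assert np.allclose(tom.to_numpy(), 1.0)

    def test_three_node_hand_evaluation(self):
        # build data with prescribed correlations via direct formula check
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(3, 30)))
        r = np.corrcoef(X)
        beta = 6
        a = ((1 + r) / 2) ** beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(1)
        expected01 = (a[0, 2] * a[2, 1] + a[0, 1]) / (min(k[0], k[1]) + 1 - a[0, 1])
        tom = net.tom_similarity(X, beta=beta)
        assert tom.iloc[0, 1] == pytest.approx(expected01)

    def test_range_on_random_sweeps(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(25, 12)))
            for beta in (1, 6, 12):
                tom = net.tom_similarity(X, beta=beta).to_numpy()
                assert tom.min() >= -1e-12 and tom.max() <= 1 + 1e-12
                assert np.allclose(np.diag(tom), 1.0)
                assert np.allclose(tom, tom.T)

    def test_unsigned_mode_and_beta_validation(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(6, 10)))
        t = net.tom_similarity(X, beta=2, signed=False)
        assert t.to_numpy().min() >= 0
        with pytest.raises(ValueError):
            net.tom_similarity(X, beta=0)


class TestModules:
    def _blocks(self, seed=5, noise=0.3, lam=1.0, n_samples=20):
        rng = np.random.default_rng(seed)
        z1, z2 = rng.normal(size=n_samples), rng.normal(size=n_samples)
        B1 = lam * z1 + rng.normal(0, noise, (30, n_samples))
        B2 = lam * z2 + rng.normal(0, noise, (30, n_samples))
        data = pd.DataFrame(np.vstack([B1, B2]),
                            index=[f"L{i}" for i in range(60)])
        return data, [0] * 30 + [1] * 30

    def test_two_block_recovery(self):
        data, truth = self._blocks()
        tom = net.tom_similarity(data)
        mods = net.detect_modules(tom, data, min_size=5)
        assert adjusted_rand_score(truth, mods.labels) == 1.0

    def test_recovery_degrades_gracefully_with_noise(self):
        aris = []
        for noise in (0.3, 1.0, 3.0):
            data, truth = self._blocks(seed=6, noise=noise)
            tom = net.tom_similarity(data)
            mods = net.detect_modules(tom, data, min_size=5)
            aris.append(adjusted_rand_score(truth, mods.labels))
        assert aris[0] >= aris[-1]
        assert aris[0] == 1.0

    def test_duplicate_module_merged(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=20)
        # two "blocks" driven by the same latent factor
        data = pd.DataFrame(
            np.vstack([z + rng.normal(0, 0.1, (20, 20)),
                       z + rng.normal(0, 0.1, (20, 20))]),
            index=[f"L{i}" for i in range(40)])
        tom = net.tom_similarity(data)
        mods = net.detect_modules(tom, data, min_size=5, merge_cut=0.15)
        assert len(mods.modules) == 1

    def test_rank_one_eigenprofile(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=25)
        block = np.outer(rng.uniform(0.5, 2, 15), z)
        noise = rng.normal(size=(15, 25))
        data = pd.DataFrame(np.vstack([block, noise]),
                            index=[f"L{i}" for i in range(30)])
        tom = net.tom_similarity(data)
        mods = net.detect_modules(tom, data, min_size=5)
        mid = mods.labels[[f"L{i}" for i in range(15)]].value_counts().idxmax()
        assert mid != 0
        eig = mods.eigenprofiles[mid]
        r = np.corrcoef(eig, z)[0, 1]
        assert abs(r) > 0.999
        assert r > 0          # oriented with the module mean profile
        assert np.linalg.norm(eig) == pytest.approx(1.0)

    def test_min_size_validation(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 8)))
        with pytest.raises(ValueError):
            net.detect_modules(net.tom_similarity(X), X, min_size=2)


class TestMembership:
    def _mods(self):
        data, _ = TestModules()._blocks(seed=9)
        tom = net.tom_similarity(data)
        mods = net.detect_modules(tom, data, min_size=5)
        return mods, data

    def test_kme_bounds_and_hubs(self):
        mods, data = self._mods()
        kme = net.membership_scores(mods, data)
        assert (kme.abs() <= 1 + 1e-12).all().all()
        for mid in mods.modules:
            hubs = mods.hubs(mid)
            members = mods.modules[mid]
            assert set(hubs) <= set(members)
            assert all(abs(kme.loc[h, mid]) >= 0.7 for h in hubs)

    def test_member_of_rank_one_module_kme_one(self):
        rng = np.random.default_rng(10)
        z = rng.normal(size=25)
        data = pd.DataFrame(
            np.vstack([np.outer(np.ones(12), z), rng.normal(size=(12, 25))]),
            index=[f"L{i}" for i in range(24)])
        mods = net.detect_modules(net.tom_similarity(data), data, min_size=5)
        mid = mods.labels[[f"L{i}" for i in range(12)]].value_counts().idxmax()
        kme = net.membership_scores(mods, data)
        # the detected module may absorb a stray background lipid, nudging
        # the eigen-profile off the shared profile by a hair
        assert (kme.loc[[f"L{i}" for i in range(12)], mid].abs() > 0.995).all()

    def test_boundary_kme_is_hub(self):
        mods, data = self._mods()
        net.membership_scores(mods, data)
        lip = mods.modules[1][0]
        mods.kme.loc[lip, 1] = 0.70
        assert lip in mods.hubs(1)


class TestModulePhenotype:
    def test_eigenprofile_phenotype_identity(self):
        mods, data = TestMembership()._mods()
        ph = pd.DataFrame({"x": mods.eigenprofiles[1]},
                          index=mods.eigenprofiles.index)
        out = net.module_phenotype_correlation(mods, ph)
        row = out[(out["module"] == 1) & (out["phenotype"] == "x")]
        assert row["r"].iloc[0] == pytest.approx(1.0)

    def test_independent_phenotype_rate_near_alpha(self):
        rng = np.random.default_rng(11)
        hits, total = 0, 0
        for seed in range(30):
            data, _ = TestModules()._blocks(seed=100 + seed)
            mods = net.detect_modules(net.tom_similarity(data), data,
                                      min_size=5)
            ph = pd.DataFrame(rng.normal(size=(len(mods.eigenprofiles), 4)),
                              index=mods.eigenprofiles.index,
                              columns=list("abcd"))
            out = net.module_phenotype_correlation(mods, ph, alpha=0.05)
            hits += out["significant"].sum()
            total += len(out)
        rate = hits / total
        assert 0.01 <= rate <= 0.12

    def test_constant_phenotype_skipped(self):
        mods, data = TestMembership()._mods()
        ph = pd.DataFrame({"const": 1.0, "ok": np.arange(20.0)},
                          index=mods.eigenprofiles.index)
        out = net.module_phenotype_correlation(mods, ph)
        assert "const" not in set(out["phenotype"])
        assert len(out.attrs["skipped_constant"]) > 0

    def test_planted_linkage_sign_recovered(self):
        """Generator phenotype linkage: the module containing the linked
        TAG block correlates with adiposity phenotypes with the planted
        (positive) sign."""
        study = sim.simulate_study(
            sim.StudyDesign(tissues=("WAT-SC",), seed=17), effects=[],
            module_strength=1.2, seed=17)
        from lipidflow.pipeline import _preprocess_tissue
        _, combined, _ = _preprocess_tissue(study, "WAT-SC")
        matrix = combined.values
        meta = study.samples[study.samples["tissue"] == "WAT-SC"]
        tom = net.tom_similarity(matrix)
        mods = net.detect_modules(tom, matrix, min_size=10)
        truth_block = study.truth.module_labels["WAT-SC"]
        block1 = [l for l in truth_block.index[truth_block == 1]
                  if l in mods.labels.index]
        mid = mods.labels[block1].value_counts().idxmax()
        assert mid != 0
        eig = mods.eigenprofiles.copy()
        eig.index = [meta.loc[s, "animal_id"] for s in eig.index]
        links = study.truth.phenotype_links.set_index("phenotype")["gamma"]
        for sex in ("male", "female"):
            aids = [a for a in eig.index
                    if study.phenotypes.loc[a, "sex"] == sex]
            sub = net.ModuleSet(labels=mods.labels,
                                eigenprofiles=eig.loc[aids],
                                beta=mods.beta, min_size=mods.min_size)
            ph = study.phenotypes.loc[aids, ["pct_fat", "leptin"]]
            out = net.module_phenotype_correlation(sub, ph)
            for _, row in out[out["module"] == mid].iterrows():
                assert np.sign(row["r"]) == np.sign(links[row["phenotype"]])
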