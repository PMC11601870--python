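"""End-to-end driver: simulate -> preprocess -> quantify -> differential ->
enrichment -> trajectory -> network.

Runs the whole analysis on a synthetic study and collects every stage's
outputs in a :class:`PipelineResult`; with an output directory the key
tables are written as TSV with fixed float formatting, so identical seeds
produce byte-identical files. Problem sizes (lipids per tissue, permutation
count) default to a desk-scale study; ``lsea`` keeps its own 10,000-
permutation default for standalone use.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import differential as diff
from . import enrichment as enr
from . import network as net
from . import preprocess as pre
from . import quantify as qn
from . import simulate as sim
from . import trajectory as traj
from .nomenclature import LipidSetCatalog

__all__ = ["PipelineResult", "run_study_pipeline", "preprocess_tissue",
           "catalog_from_universe"]


def catalog_from_universe(universe: pd.DataFrame,
                          min_size: int = 10) -> LipidSetCatalog:
    """Class sets keyed by feature id, from simulated feature metadata."""
    ann = universe[(universe["msi_level"] <= 3) & ~universe["is_istd"]
                   & universe["lipid_class"].notna()]
    sets = {cls: sorted(ids) for cls, ids in
            ann.groupby("lipid_class").groups.items()
            if len(ids) >= min_size}
    return LipidSetCatalog(sets={k: list(v) for k, v in sets.items()},
                           set_kind="class")


@dataclass
class PipelineResult:
    study: sim.SimulatedStudy
    normalized: dict                       # tissue -> NormalizedMatrix values
    targeted: dict                         # tissue -> TargetedResult
    quant: dict                            # tissue -> QuantTable
    class_fractions: dict                  # tissue -> DataFrame
    pcpe: dict                             # tissue -> Series
    timewise: pd.DataFrame
    training_f: pd.DataFrame
    sex_contrasts: pd.DataFrame
    lsea_f: pd.DataFrame
    lsea_timewise: pd.DataFrame
    clusters: dict                         # tissue -> ClusterResult
    cluster_ora: pd.DataFrame
    sex_trajectory_r: pd.DataFrame
    networks: dict                         # sex -> NetworkGraph
    modules: dict                          # tissue -> ModuleSet
    module_phenotypes: pd.DataFrame
    qc_logs: dict = field(default_factory=dict)


def _preprocess_tissue(study: sim.SimulatedStudy, tissue: str):
    """Drift-correct, filter, de-duplicate and normalize one tissue."""
    tables, logs = {}, {}
    for mode in ("positive", "negative"):
        t = study.untargeted[(tissue, mode)]
        t, drift_rep = pre.drift_correct(t)
        t, removal = pre.qc_filter(t)
        tables[mode] = t
        logs[mode] = {"drift": drift_rep, "qc_removal": removal}
    pos, neg, degen_log = pre.remove_degenerate(tables["positive"],
                                                tables["negative"])
    tables = {"positive": pos, "negative": neg}
    norms = []
    for mode in ("positive", "negative"):
        t = tables[mode]
        annotated = t.features.index[(t.features["msi_level"] <= 3)]
        norms.append(pre.normalize(t.subset(annotated)))
    combined = pre.combine_modes(*norms)
    # complete the matrix for the vectorized statistics downstream
    filled = qn.nipals_impute(combined.values, rank=2, tol=1e-6,
                              max_iter=100, nonnegative=False)
    combined.provenance = combined.provenance.mask(
        combined.values.isna() & filled.notna(), "imputed")
    combined.values = filled
    logs["degenerate"] = degen_log
    return tables, combined, logs


preprocess_tissue = _preprocess_tissue


def run_study_pipeline(seed: int = 0,
                       design: Optional[sim.StudyDesign] = None,
                       n_perm: int = 1000,
                       c_clusters: int = 9,
                       fdr: float = 0.05,
                       outdir: Optional[str] = None) -> PipelineResult:
    """Run the full analysis on a simulated study.

    All randomness (simulation, LSEA permutations, clustering restarts)
    derives from ``seed``.
    """
    if design is None:
        design = sim.StudyDesign(seed=seed)
    else:
        design = sim.StudyDesign(tissues=design.tissues, sexes=design.sexes,
                                 groups=design.groups,
                                 n_per_cell=design.n_per_cell, seed=seed)
    study = sim.simulate_study(design)
    samples = study.samples
    catalog = catalog_from_universe(study.universe)
    timepoints = [g for g in design.groups if g != "SED"]

    normalized, quant, fractions, pcpe = {}, {}, {}, {}
    targeted = {}
    qc_logs = {}
    tw_frames, f_frames, sx_frames = [], [], []
    lsea_f_rows, lsea_tw_rows = [], []
    clusters, modules = {}, {}
    ora_rows, sexr_rows, modpheno_rows = [], [], []

    istd_catalog = qn.build_istd_catalog(
        study.universe, study.istd_concentrations,
        fallbacks=sim.ISTD_FALLBACKS)

    for ti, tissue in enumerate(design.tissues):
        tables, combined, logs = _preprocess_tissue(study, tissue)
        qc_logs[tissue] = logs
        normalized[tissue] = combined
        meta = samples[samples["tissue"] == tissue]

        # semi-absolute quantification on the cleaned tables
        is_plasma = tissue.upper() == "PLASMA"
        amount = (qn.PLASMA_SAMPLE_VOLUME_UL if is_plasma
                  else qn.TISSUE_SAMPLE_AMOUNT_MG)
        volume = (qn.PLASMA_EXTRACT_VOLUME_UL if is_plasma
                  else qn.TISSUE_EXTRACT_VOLUME_UL)
        unit = "ug/uL" if is_plasma else "ug/mg"
        parts = []
        for mode in ("positive", "negative"):
            t = study.untargeted[(tissue, mode)]
            keep = [f for f in t.features.index
                    if f in tables[mode].features.index
                    or t.features.loc[f, "is_istd"]]
            parts.append(qn.istd_quantify(t.subset(keep), istd_catalog,
                                          sample_amount=amount,
                                          extract_volume=volume, unit=unit))
        qt = qn.QuantTable(
            values=pd.concat([p.values for p in parts]),
            provenance=pd.concat([p.provenance for p in parts]),
            classes=pd.concat([p.classes for p in parts]),
            unit=unit, tissue=tissue)
        qt, _ = qn.mad_class_filter(qt, mad_mult=5.0, special={"WAT-SC": 15.0})
        qt = qn.nipals_impute(qt, rank=2, tol=1e-6, max_iter=100)
        quant[tissue] = qt
        _, fractions[tissue] = qn.class_composition(qt)
        pcpe[tissue] = qn.pcpe_ratio(qt)

        # targeted oxylipin/NAE panel: CV/missingness filters + KNN + log2
        tt = study.targeted[tissue]
        targeted[tissue] = pre.targeted_qc(tt["conc"], tt["qc_conc"],
                                           tt["qc_rt"])

        # differential: per sex timewise + F; joint sex contrasts
        matrix = combined.values
        sex_traj = {}
        for sex in design.sexes:
            cols = [c for c in matrix.columns if meta.loc[c, "sex"] == sex]
            sub = matrix[cols]
            tw = diff.timewise_results(sub, meta, timepoints=timepoints)
            tw["tissue"], tw["sex"] = tissue, sex
            tw_frames.append(tw)
            ftab = diff.training_f_results(sub, meta, timepoints=timepoints)
            ftab["tissue"], ftab["sex"] = tissue, sex
            f_frames.append(ftab)

            # enrichment rankings
            rk_f = enr.make_ranked_list(ftab.set_index("lipid")["F"])
            lf = enr.lsea(rk_f, catalog, n_perm=n_perm, seed=seed + ti,
                          score_type="pos")
            lf["tissue"], lf["sex"], lf["ranking"] = tissue, sex, "F"
            lsea_f_rows.append(lf)
            for tp in timepoints:
                sub_tw = tw[tw["timepoint"] == tp].set_index("lipid")
                rk = enr.make_ranked_list(enr.signed_logp_metric(sub_tw))
                lt = enr.lsea(rk, catalog, n_perm=n_perm, seed=seed + ti)
                lt["tissue"], lt["sex"], lt["timepoint"] = tissue, sex, tp
                lsea_tw_rows.append(lt)

            sex_traj[sex] = traj.logfc_trajectories(tw, timepoints=timepoints)

        sx = diff.sex_contrast_results(matrix, meta, timepoints=timepoints,
                                       sexes=design.sexes)
        sx["tissue"] = tissue
        sx_frames.append(sx)

        # male-female trajectory concordance
        r = traj.pairwise_trajectory_correlations(sex_traj[design.sexes[0]],
                                                  sex_traj[design.sexes[1]])
        rdf = r.rename("r").reset_index().rename(columns={"index": "lipid"})
        rdf["tissue"] = tissue
        rdf["lipid_class"] = rdf["lipid"].map(study.universe["lipid_class"])
        sexr_rows.append(rdf)

        # trajectory clustering on two-sex group means
        tmat = traj.build_trajectory_matrix(matrix, meta)
        cres = traj.FuzzyCMeans(min(c_clusters, len(tmat) - 1), m=1.5,
                                seed=seed + ti, n_init=5).fit(tmat)
        clusters[tissue] = cres
        core = cres.core
        background = list(tmat.index)
        for cid in cres.centroids.index:
            members = list(core.index[core == cid])
            if len(members) < 3:
                continue
            tab = enr.ora_catalog(members, catalog, background)
            if len(tab):
                tab["tissue"], tab["cluster"] = tissue, cid
                ora_rows.append(tab)

        # WGCNA-style modules on the full two-sex matrix
        tom = net.tom_similarity(matrix, beta=6, signed=True)
        mods = net.detect_modules(tom, matrix, min_size=10, merge_cut=0.15)
        net.membership_scores(mods, matrix)
        modules[tissue] = mods
        if not mods.eigenprofiles.empty:
            eig = mods.eigenprofiles.copy()
            eig.index = [meta.loc[s, "animal_id"] for s in eig.index]
            for sex in design.sexes:
                aids = [a for a in eig.index
                        if study.phenotypes.loc[a, "sex"] == sex]
                msub = net.ModuleSet(labels=mods.labels,
                                     eigenprofiles=eig.loc[aids],
                                     beta=mods.beta, min_size=mods.min_size)
                ph = study.phenotypes.loc[aids,
                                          [c for c in study.phenotypes.columns
                                           if c not in ("sex", "group")]]
                mp = net.module_phenotype_correlation(msub, ph)
                mp["tissue"], mp["sex"] = tissue, sex
                modpheno_rows.append(mp)

    # cross-tissue sample-level networks, one per sex
    networks = {}
    for sex in design.sexes:
        mats = {}
        for tissue in design.tissues:
            meta = samples[samples["tissue"] == tissue]
            cols = [c for c in normalized[tissue].values.columns
                    if meta.loc[c, "sex"] == sex]
            m = normalized[tissue].values[cols]
            m.columns = [meta.loc[c, "animal_id"] for c in cols]
            mats[tissue] = m
        networks[sex] = net.build_correlation_network(mats, alpha=0.05)

    result = PipelineResult(
        study=study,
        normalized={t: m.values for t, m in normalized.items()},
        targeted=targeted,
        quant=quant,
        class_fractions=fractions,
        pcpe=pcpe,
        timewise=pd.concat(tw_frames, ignore_index=True),
        training_f=pd.concat(f_frames, ignore_index=True),
        sex_contrasts=pd.concat(sx_frames, ignore_index=True),
        lsea_f=pd.concat(lsea_f_rows, ignore_index=True),
        lsea_timewise=pd.concat(lsea_tw_rows, ignore_index=True),
        clusters=clusters,
        cluster_ora=(pd.concat(ora_rows, ignore_index=True)
                     if ora_rows else pd.DataFrame()),
        sex_trajectory_r=pd.concat(sexr_rows, ignore_index=True),
        networks=networks,
        modules=modules,
        module_phenotypes=(pd.concat(modpheno_rows, ignore_index=True)
                           if modpheno_rows else pd.DataFrame()),
        qc_logs=qc_logs,
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def write_outputs(result: PipelineResult, outdir: str) -> list[str]:
    """Write the key result tables as TSV with fixed formatting."""
    os.makedirs(outdir, exist_ok=True)
    written = []

    def w(df: pd.DataFrame, name: str):
        path = os.path.join(outdir, name)
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path)

    w(result.timewise.drop(columns=["contrast"], errors="ignore"),
      "differential_timewise.tsv")
    w(result.training_f.drop(columns=["contrast"], errors="ignore"),
      "differential_training_f.tsv")
    w(result.sex_contrasts, "differential_sex_contrasts.tsv")
    w(result.lsea_f.drop(columns=["leading_edge"]), "lsea_training_f.tsv")
    w(result.lsea_timewise.drop(columns=["leading_edge"]),
      "lsea_timewise.tsv")
    w(result.sex_trajectory_r, "sex_trajectory_correlations.tsv")
    if len(result.cluster_ora):
        w(result.cluster_ora, "cluster_ora.tsv")
    if len(result.module_phenotypes):
        w(result.module_phenotypes, "module_phenotype_correlations.tsv")
    mem = pd.concat([
        pd.DataFrame({"tissue": t, "lipid": c.membership.index,
                      "core_cluster": c.core})
        for t, c in result.clusters.items()], ignore_index=True)
    w(mem, "cluster_cores.tsv")
    labels = pd.concat([
        pd.DataFrame({"tissue": t, "lipid": m.labels.index,
                      "module": m.labels.to_numpy()})
        for t, m in result.modules.items()], ignore_index=True)
    w(labels, "module_labels.tsv")
    for sex, g in result.networks.items():
        counts = g.tissue_pair_counts()
        counts["tissue_pair"] = counts["tissue_pair"].map(
            lambda p: f"{p[0]}|{p[1]}")
        counts["sex"] = sex
        w(counts, f"network_edge_counts_{sex}.tsv")
        deg = g.degree().rename("degree").reset_index()
        deg["sex"] = sex
        w(deg, f"network_degree_{sex}.tsv")
    frac = pd.concat([f.assign(tissue=t, lipid_class=f.index)
                      for t, f in result.class_fractions.items()],
                     ignore_index=True)
    w(frac, "class_fractions.tsv")
    targ = pd.concat([r.normalized.assign(tissue=t, analyte=r.normalized.index)
                      for t, r in result.targeted.items()],
                     ignore_index=True)
    w(targ, "targeted_normalized.tsv")
    return written
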