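"""Untargeted feature-table preprocessing.

Raw per-tissue, per-ionization-mode feature tables (peak areas over study,
pooled-QC and blank injections) are taken through: per-feature linear drift
correction against the pooled QCs, blank/QC-based feature filtering, removal
of features detected redundantly in both ESI modes, log2 normalization
(feature standardization then sample median-centering), and sample outlier
screening. Cross-tissue PCA and one-way variance components support the
tissue-profile comparisons; ``targeted_qc`` applies the targeted assay's
CV/missingness filters with KNN imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "FeatureTable",
    "NormalizedMatrix",
    "OutlierReport",
    "drift_correct",
    "qc_filter",
    "remove_degenerate",
    "normalize",
    "combine_modes",
    "detect_outlier_samples",
    "cross_tissue_pca",
    "variance_components",
    "targeted_qc",
]


@dataclass
class FeatureTable:
    """Features-by-injections peak areas with injection and feature metadata.

    ``areas`` holds nonnegative peak areas (NaN = missing) with one column
    per injection; ``injections`` is indexed by injection id with columns
    ``order`` (strictly increasing, unique), ``role`` (study/QC/blank) and
    ``sample_id`` (study injections only); ``features`` is indexed by
    feature id with columns ``name``, ``msi_level``, ``esi_mode``,
    ``is_istd``.
    """

    areas: pd.DataFrame
    features: pd.DataFrame
    injections: pd.DataFrame
    tissue: str = ""
    esi_mode: str = "positive"

    def __post_init__(self):
        if list(self.areas.columns) != list(self.injections.index):
            raise ValueError("area columns must match injection index")
        if not self.areas.index.equals(self.features.index):
            raise ValueError("area rows must match feature index")
        orders = self.injections["order"].to_numpy()
        if len(np.unique(orders)) != len(orders) or np.any(np.diff(orders) <= 0):
            order = self.injections["order"].sort_values()
            if order.duplicated().any():
                raise ValueError("injection orders must be unique")
            self.injections = self.injections.loc[order.index]
            self.areas = self.areas[order.index]
        roles = set(self.injections["role"])
        if not roles <= {"study", "QC", "blank"}:
            raise ValueError(f"unknown injection roles: {roles - {'study', 'QC', 'blank'}}")
        study = self.injections[self.injections["role"] == "study"]
        if study["sample_id"].isna().any():
            raise ValueError("every study injection needs a sample_id")

    def _cols(self, role: str) -> pd.Index:
        return self.injections.index[self.injections["role"] == role]

    @property
    def study_areas(self) -> pd.DataFrame:
        """Study-injection areas with sample ids as columns."""
        cols = self._cols("study")
        out = self.areas[cols].copy()
        out.columns = self.injections.loc[cols, "sample_id"].to_list()
        return out

    @property
    def qc_areas(self) -> pd.DataFrame:
        return self.areas[self._cols("QC")]

    @property
    def blank_areas(self) -> pd.DataFrame:
        return self.areas[self._cols("blank")]

    def subset(self, feature_ids) -> "FeatureTable":
        return FeatureTable(
            areas=self.areas.loc[feature_ids],
            features=self.features.loc[feature_ids],
            injections=self.injections,
            tissue=self.tissue,
            esi_mode=self.esi_mode,
        )

    def with_areas(self, areas: pd.DataFrame) -> "FeatureTable":
        return FeatureTable(areas=areas, features=self.features,
                            injections=self.injections, tissue=self.tissue,
                            esi_mode=self.esi_mode)


@dataclass
class NormalizedMatrix:
    """Lipids-by-samples normalized log2 abundances with cell provenance."""

    values: pd.DataFrame
    provenance: pd.DataFrame            # "observed" | "imputed"
    zero_variance: list = field(default_factory=list)
    tissue: str = ""

    def __post_init__(self):
        if self.values.shape != self.provenance.shape:
            raise ValueError("provenance must match values shape")


def _qc_cv(table: FeatureTable) -> pd.Series:
    """Coefficient of variation over raw pooled-QC areas, per feature."""
    qc = table.qc_areas
    mean = qc.mean(axis=1)
    sd = qc.std(axis=1, ddof=1)
    return sd / mean


def drift_correct(table: FeatureTable):
    """Correct per-feature injection-order drift against the pooled QCs.

    For each feature with at least 3 observed QC areas, an OLS line of QC
    area versus injection order is fitted; every area is rescaled by
    ``fit(ref) / fit(order)`` where ``ref`` is the median observed QC
    injection order for that feature. Features with fewer than 3 QC
    observations, or whose fitted line is nonpositive at any injection,
    pass through unchanged and are flagged.

    Returns the corrected table and a per-feature report with columns
    ``corrected`` (bool) and ``reason``.
    """
    qc_cols = table._cols("QC")
    if len(qc_cols) == 0:
        raise ValueError("drift correction needs pooled-QC injections")
    orders = table.injections["order"].to_numpy(float)
    qc_orders = table.injections.loc[qc_cols, "order"].to_numpy(float)
    Q = table.areas[qc_cols].to_numpy(float)         # features x nQC
    obs = np.isfinite(Q)
    nobs = obs.sum(axis=1)

    corrected = np.zeros(table.areas.shape[0], dtype=bool)
    reasons = np.array(["insufficient_qc"] * table.areas.shape[0], dtype=object)
    new_areas = table.areas.to_numpy(float).copy()

    enough = nobs >= 3
    # per-feature OLS of QC area on order, over observed QCs
    Ow = np.where(obs, qc_orders[None, :], np.nan)
    mean_o = np.nanmean(Ow, axis=1)
    mean_q = np.nanmean(np.where(obs, Q, np.nan), axis=1)
    do = Ow - mean_o[:, None]
    dq = np.where(obs, Q, np.nan) - mean_q[:, None]
    var_o = np.nansum(np.where(obs, do**2, 0.0), axis=1)
    cov = np.nansum(np.where(obs, do * dq, 0.0), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(var_o > 0, cov / var_o, 0.0)
    intercept = mean_q - slope * mean_o
    ref = np.nanmedian(Ow, axis=1)
    fit_ref = intercept + slope * ref

    fits = intercept[:, None] + slope[:, None] * orders[None, :]
    bad_fit = (fits <= 0).any(axis=1) | ~np.isfinite(fit_ref) | (fit_ref <= 0)

    ok = enough & ~bad_fit
    with np.errstate(invalid="ignore", divide="ignore"):
        factor = fits[ok] / fit_ref[ok, None]
    new_areas[ok] = new_areas[ok] / factor
    corrected[ok] = True
    reasons[ok] = ""
    reasons[enough & bad_fit] = "nonpositive_fit"

    out = table.with_areas(pd.DataFrame(new_areas, index=table.areas.index,
                                        columns=table.areas.columns))
    report = pd.DataFrame({"corrected": corrected, "reason": reasons},
                          index=table.areas.index)
    return out, report


def qc_filter(table: FeatureTable, blank_ratio: float = 5.0,
              qc_presence: float = 0.5, qc_cv_max: float = 0.30):
    """Remove features failing any of the blank/QC quality rules.

    Rule 1: mean study area below ``blank_ratio`` times the blank background
    (mean blank area, missing treated as 0). Rule 2: observed in fewer than
    ``qc_presence`` of the pooled QCs. Rule 3: QC coefficient of variation
    above ``qc_cv_max`` (on raw areas). Returns the filtered table and a
    removal log listing every rule that fired per removed feature.
    """
    if len(table._cols("blank")) < 1 or len(table._cols("QC")) < 2:
        raise ValueError("need >= 1 blank and >= 2 QC injections")
    blank_bg = table.blank_areas.fillna(0.0).mean(axis=1)
    study_mean = table.study_areas.mean(axis=1).fillna(0.0)
    qc = table.qc_areas
    presence = qc.notna().mean(axis=1)
    cv = _qc_cv(table)

    fired = {}
    for fid in table.areas.index:
        rules = []
        if study_mean[fid] < blank_ratio * blank_bg[fid]:
            rules.append("blank_ratio")
        if presence[fid] < qc_presence:
            rules.append("qc_presence")
        if np.isfinite(cv[fid]) and cv[fid] > qc_cv_max:
            rules.append("qc_cv")
        if rules:
            fired[fid] = rules
    keep = [f for f in table.areas.index if f not in fired]
    log = pd.DataFrame({
        "feature_id": list(fired),
        "rules": [",".join(v) for v in fired.values()],
    })
    return table.subset(keep), log


def remove_degenerate(pos: FeatureTable, neg: FeatureTable):
    """Drop redundant annotations detected in both ESI modes.

    For every annotated (MSI 1-3) name present in both tables, the occurrence
    with the higher pooled-QC CV is removed; ties keep the positive-mode
    feature and are flagged. Returns the filtered (pos, neg) tables and a log.
    Applying the operation twice is a no-op: after the first pass no name is
    shared between modes.
    """
    def named(t: FeatureTable) -> pd.Series:
        f = t.features
        ok = (f["msi_level"] <= 3) & f["name"].notna()
        return f.loc[ok, "name"]

    cv_pos, cv_neg = _qc_cv(pos), _qc_cv(neg)
    names_pos, names_neg = named(pos), named(neg)
    shared = set(names_pos) & set(names_neg)
    drop_pos, drop_neg, log = [], [], []
    for name in sorted(shared):
        fp = names_pos.index[names_pos == name]
        fn = names_neg.index[names_neg == name]
        best_p = cv_pos[fp].min()
        best_n = cv_neg[fn].min()
        tie = np.isclose(best_p, best_n)
        if best_p <= best_n or tie:
            keep_mode, keep_id = "positive", cv_pos[fp].idxmin()
            drop_neg.extend(fn)
            drop_pos.extend(i for i in fp if i != keep_id)
        else:
            keep_mode, keep_id = "negative", cv_neg[fn].idxmin()
            drop_pos.extend(fp)
            drop_neg.extend(i for i in fn if i != keep_id)
        log.append({"name": name, "kept_mode": keep_mode, "kept_id": keep_id,
                    "tie": bool(tie)})
    pos_out = pos.subset([f for f in pos.areas.index if f not in set(drop_pos)])
    neg_out = neg.subset([f for f in neg.areas.index if f not in set(drop_neg)])
    return pos_out, neg_out, pd.DataFrame(log)


def normalize(table: FeatureTable, drop_istd: bool = True) -> NormalizedMatrix:
    """log2 -> feature standardization (median 0, sd 1) -> sample centering.

    Operates on study injections only. Nonpositive areas are treated as
    missing. Zero-variance features get sd 1 and are flagged. After the final
    per-sample median subtraction every sample median is exactly 0 on the
    observed cells.
    """
    X = table.study_areas
    if drop_istd and "is_istd" in table.features:
        X = X.loc[~table.features["is_istd"].astype(bool)]
    vals = X.to_numpy(float)
    vals[~(vals > 0)] = np.nan
    logged = np.log2(vals)
    med = np.nanmedian(logged, axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(logged, axis=1, ddof=1, keepdims=True)
    zero_var = (~np.isfinite(sd)) | (sd == 0)
    sd = np.where(zero_var, 1.0, sd)
    std = (logged - med) / sd
    samp_med = np.nanmedian(std, axis=0, keepdims=True)
    centered = std - samp_med
    values = pd.DataFrame(centered, index=X.index, columns=X.columns)
    prov = pd.DataFrame(np.where(np.isfinite(centered), "observed", "missing"),
                        index=X.index, columns=X.columns)
    return NormalizedMatrix(values=values, provenance=prov,
                            zero_variance=list(X.index[zero_var.ravel()]),
                            tissue=table.tissue)


def combine_modes(*matrices: NormalizedMatrix) -> NormalizedMatrix:
    """Row-concatenate per-mode normalized matrices over shared samples."""
    cols = matrices[0].values.columns
    for m in matrices[1:]:
        if set(m.values.columns) != set(cols):
            raise ValueError("modes must cover the same samples")
    values = pd.concat([m.values[cols] for m in matrices], axis=0)
    prov = pd.concat([m.provenance[cols] for m in matrices], axis=0)
    zv = [f for m in matrices for f in m.zero_variance]
    return NormalizedMatrix(values=values, provenance=prov, zero_variance=zv,
                            tissue=matrices[0].tissue)


@dataclass
class OutlierReport:
    flagged: list
    median_correlation: pd.Series
    pc_scores: pd.DataFrame
    pc_flags: pd.DataFrame
    retained_pcs: list


def detect_outlier_samples(table: FeatureTable,
                           normalized: Optional[NormalizedMatrix] = None,
                           corr_min: float = 0.75, iqr_mult: float = 3.0,
                           n_pcs: int = 3,
                           min_pc_var: float = 0.075) -> OutlierReport:
    """Flag suspect study samples; removal is the caller's decision.

    A sample is flagged when (a) its median Pearson correlation to the other
    samples — computed on raw peak intensities — falls below ``corr_min``, or
    (b) any of its scores on the first ``n_pcs`` principal components
    (components kept only when they explain at least ``min_pc_var`` of
    variance) lies outside the ``iqr_mult``-times-IQR fences. The PCA runs
    on log2 feature-standardized data *before* sample median-centering
    (centering would erase a uniform sample shift, exactly the signature
    the screen must catch); ``normalized`` overrides that default input.
    """
    raw = table.study_areas
    if raw.shape[1] < 4:
        raise ValueError("need at least 4 study samples")
    corr = raw.corr(method="pearson")          # pairwise-complete
    np.fill_diagonal(corr.values, np.nan)
    med_corr = corr.median(axis=1)

    if normalized is not None:
        Z = normalized.values.to_numpy(float).T
    else:
        vals = raw.to_numpy(float)
        vals[~(vals > 0)] = np.nan
        logged = np.log2(vals)
        med = np.nanmedian(logged, axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            sd = np.nanstd(logged, axis=1, ddof=1, keepdims=True)
        sd = np.where((sd == 0) | ~np.isfinite(sd), 1.0, sd)
        Z = ((logged - med) / sd).T            # samples x lipids
    Z = np.where(np.isfinite(Z), Z, 0.0)
    k = min(n_pcs, Z.shape[0] - 1, Z.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Z)
    evr = pca.explained_variance_ratio_
    retained = [i for i in range(k) if evr[i] >= min_pc_var]

    samples = list(raw.columns)
    pc_flags = pd.DataFrame(False, index=samples,
                            columns=[f"PC{i + 1}" for i in range(k)])
    for i in retained:
        s = scores[:, i]
        q1, q3 = np.percentile(s, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - iqr_mult * iqr, q3 + iqr_mult * iqr
        pc_flags.iloc[:, i] = (s < lo) | (s > hi)

    flagged = sorted(set(med_corr.index[med_corr < corr_min])
                     | set(pc_flags.index[pc_flags.any(axis=1)]))
    return OutlierReport(
        flagged=flagged,
        median_correlation=med_corr,
        pc_scores=pd.DataFrame(scores, index=samples,
                               columns=[f"PC{i + 1}" for i in range(k)]),
        pc_flags=pc_flags,
        retained_pcs=[f"PC{i + 1}" for i in retained],
    )


@dataclass
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    lipids: list


def cross_tissue_pca(tissue_matrices: Mapping[str, pd.DataFrame],
                     min_tissues: int = 5, n_components: int = 4) -> PcaResult:
    """PCA over samples of all tissues on shared lipids.

    Input matrices are lipid-name-indexed log2 abundances (unstandardized —
    feature scales are part of a tissue's identity). Lipids present in at
    least ``min_tissues`` tissues are kept; missing values are replaced by
    the lipid's minimum observed level; samples are median-centered.
    """
    if len(tissue_matrices) < 2:
        raise ValueError("need at least 2 tissues")
    counts: dict[str, int] = {}
    for mat in tissue_matrices.values():
        for lip in mat.index[mat.notna().any(axis=1)]:
            counts[lip] = counts.get(lip, 0) + 1
    lipids = sorted(l for l, c in counts.items() if c >= min_tissues)
    if not lipids:
        raise ValueError(f"no lipid present in >= {min_tissues} tissues")

    blocks = []
    for tissue, mat in tissue_matrices.items():
        sub = mat.reindex(lipids)
        sub.columns = pd.MultiIndex.from_product([[tissue], mat.columns],
                                                 names=["tissue", "sample"])
        blocks.append(sub)
    combined = pd.concat(blocks, axis=1)
    row_min = combined.min(axis=1)
    combined = combined.apply(lambda col: col.fillna(row_min))
    combined = combined - combined.median(axis=0)

    X = combined.to_numpy(float).T            # samples x lipids
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    return PcaResult(
        scores=pd.DataFrame(scores, index=combined.columns,
                            columns=[f"PC{i + 1}" for i in range(k)]),
        loadings=pd.DataFrame(pca.components_.T, index=lipids,
                              columns=[f"PC{i + 1}" for i in range(k)]),
        explained_variance_ratio=pca.explained_variance_ratio_,
        lipids=lipids,
    )


def variance_components(scores: pd.Series, factor: pd.Series) -> float:
    """Fraction of variance between factor levels (one-way random effects).

    Method-of-moments: sigma2_between = max(0, (MSB − MSW) / n0) with the
    unbalanced-design average group size n0; returns
    sigma2_between / (sigma2_between + MSW).
    """
    y = pd.Series(scores).astype(float)
    g = pd.Series(factor).loc[y.index]
    sizes = g.value_counts()
    if (sizes < 2).any():
        raise ValueError("every group needs at least 2 samples")
    k, N = len(sizes), len(y)
    if k < 2:
        raise ValueError("need at least 2 groups")
    grand = y.mean()
    means = y.groupby(g).mean()
    msb = float((sizes * (means - grand) ** 2).sum() / (k - 1))
    ssw = float(((y - means[g].to_numpy()) ** 2).sum())
    msw = ssw / (N - k)
    n0 = (N - float((sizes**2).sum()) / N) / (k - 1)
    sb = max(0.0, (msb - msw) / n0)
    total = sb + msw
    return sb / total if total > 0 else 0.0


@dataclass
class TargetedResult:
    concentrations: pd.DataFrame
    normalized: pd.DataFrame
    removal_log: pd.DataFrame
    imputed: pd.DataFrame
    mean_fallback: list


def targeted_qc(conc: pd.DataFrame, qc_conc: Optional[pd.DataFrame] = None,
                qc_rt: Optional[pd.DataFrame] = None,
                conc_cv_max: float = 1.0, rt_cv_max: float = 0.10,
                miss_max: float = 0.20, k: int = 10) -> TargetedResult:
    """Targeted assay QC filters plus feature-space KNN imputation.

    Removes analytes with pooled-QC concentration CV above ``conc_cv_max``,
    retention-time CV above ``rt_cv_max``, or study missingness above
    ``miss_max``; remaining missing cells are imputed as the average of the
    ``k`` nearest analytes (Euclidean distance over mutually observed
    samples, scaled to the common-sample count) that are observed in that
    sample. With fewer than ``k`` eligible neighbors the analyte mean is
    used (flagged). The imputed table is then log2-transformed, feature
    standardized and sample median-centered.
    """
    removal = []
    keep = list(conc.index)
    if qc_conc is not None:
        cv = qc_conc.std(axis=1, ddof=1) / qc_conc.mean(axis=1)
        for a in conc.index:
            if a in cv.index and np.isfinite(cv[a]) and cv[a] > conc_cv_max:
                removal.append({"analyte": a, "rule": "conc_cv"})
    if qc_rt is not None:
        rcv = qc_rt.std(axis=1, ddof=1) / qc_rt.mean(axis=1)
        for a in conc.index:
            if a in rcv.index and np.isfinite(rcv[a]) and rcv[a] > rt_cv_max:
                removal.append({"analyte": a, "rule": "rt_cv"})
    miss = conc.isna().mean(axis=1)
    for a in conc.index:
        if miss[a] > miss_max:
            removal.append({"analyte": a, "rule": "missingness"})
    removed = {r["analyte"] for r in removal}
    keep = [a for a in keep if a not in removed]
    sub = conc.loc[keep].copy()

    X = sub.to_numpy(float)
    obs = np.isfinite(X)
    imputed_mask = pd.DataFrame(False, index=sub.index, columns=sub.columns)
    fallback = []
    n_feat = X.shape[0]
    # pairwise feature distances over mutually observed samples
    dist = np.full((n_feat, n_feat), np.inf)
    for i in range(n_feat):
        for j in range(i + 1, n_feat):
            common = obs[i] & obs[j]
            if common.sum() >= 2:
                d2 = np.mean((X[i, common] - X[j, common]) ** 2)
                dist[i, j] = dist[j, i] = np.sqrt(d2)
    for i in range(n_feat):
        miss_cols = np.where(~obs[i])[0]
        if miss_cols.size == 0:
            continue
        order = np.argsort(dist[i], kind="stable")
        for c in miss_cols:
            neighbors = [j for j in order
                         if np.isfinite(dist[i, j]) and obs[j, c]]
            if len(neighbors) < k:
                X[i, c] = np.nanmean(np.where(obs[i], X[i], np.nan))
                if sub.index[i] not in fallback:
                    fallback.append(sub.index[i])
            else:
                X[i, c] = np.mean([X[j, c] for j in neighbors[:k]])
            imputed_mask.iloc[i, c] = True

    filled = pd.DataFrame(X, index=sub.index, columns=sub.columns)
    logv = np.log2(np.where(X > 0, X, np.nan))
    med = np.nanmedian(logv, axis=1, keepdims=True)
    sd = np.nanstd(logv, axis=1, ddof=1, keepdims=True)
    sd = np.where((sd == 0) | ~np.isfinite(sd), 1.0, sd)
    std = (logv - med) / sd
    std = std - np.nanmedian(std, axis=0, keepdims=True)
    normalized = pd.DataFrame(std, index=sub.index, columns=sub.columns)
    return TargetedResult(
        concentrations=filled,
        normalized=normalized,
        removal_log=pd.DataFrame(removal),
        imputed=imputed_mask,
        mean_fallback=fallback,
    )
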