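"""Internal-standard semi-absolute quantification and composition summaries.

Peak areas are converted to concentrations by ratio to the spiked,
isotope-labelled internal standard (ISTD) of the lipid's own class and ESI
mode (or a designated structurally-closest fallback), times the known spiked
concentration, scaled by extraction volume over tissue mass (ug/mg) or
plasma volume (ug/uL). Class-level sample outliers are removed on the
class-sum scale using unscaled median absolute deviations; remaining holes
are filled by NIPALS-PCA imputation. Composition summaries (class
fractions, PC:PE ratio, DHA:ARA ratios) and targeted standard-curve
calibration round out the stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .nomenclature import (ARA_CHAIN, DHA_CHAIN, LipidAnnotation,
                           select_pufa_species)
from .preprocess import FeatureTable

__all__ = [
    "IstdEntry",
    "IstdCatalog",
    "QuantTable",
    "build_istd_catalog",
    "istd_quantify",
    "mad_class_filter",
    "nipals_impute",
    "class_composition",
    "pcpe_ratio",
    "dha_ara_ratio",
    "calibrate_targeted",
    "TISSUE_SAMPLE_AMOUNT_MG",
    "TISSUE_EXTRACT_VOLUME_UL",
    "PLASMA_SAMPLE_VOLUME_UL",
    "PLASMA_EXTRACT_VOLUME_UL",
]

# extraction geometry: 10 mg tissue in 400 uL solvent; 25 uL plasma in 75 uL
TISSUE_SAMPLE_AMOUNT_MG = 10.0
TISSUE_EXTRACT_VOLUME_UL = 400.0
PLASMA_SAMPLE_VOLUME_UL = 25.0
PLASMA_EXTRACT_VOLUME_UL = 75.0


@dataclass(frozen=True)
class IstdEntry:
    istd_id: str
    istd_name: str
    esi_mode: str
    conc_ug_ml: float
    fallback: bool = False


@dataclass
class IstdCatalog:
    """Mapping lipid class -> the internal standard that quantifies it."""

    by_class: dict[str, IstdEntry]

    def entry(self, lipid_class: str) -> IstdEntry:
        try:
            return self.by_class[lipid_class]
        except KeyError:
            raise KeyError(f"no ISTD configured for class {lipid_class!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"lipid_class": c, "istd_id": e.istd_id, "istd_name": e.istd_name,
             "esi_mode": e.esi_mode, "conc_ug_ml": e.conc_ug_ml,
             "fallback": e.fallback}
            for c, e in sorted(self.by_class.items())])


def build_istd_catalog(features: pd.DataFrame, istd_conc: pd.Series,
                       fallbacks: Optional[Mapping[str, str]] = None) -> IstdCatalog:
    """Build the class->ISTD map from feature metadata and spiked
    concentrations; ``fallbacks`` maps classes without their own standard to
    the class whose ISTD they borrow."""
    istds = features[features["is_istd"].astype(bool)]
    own = {}
    for fid, row in istds.iterrows():
        own[row["lipid_class"]] = IstdEntry(
            istd_id=fid, istd_name=row["name"], esi_mode=row["esi_mode"],
            conc_ug_ml=float(istd_conc[fid]), fallback=False)
    by_class = dict(own)
    for cls, src in (fallbacks or {}).items():
        if src in own:
            e = own[src]
            by_class[cls] = IstdEntry(e.istd_id, e.istd_name, e.esi_mode,
                                      e.conc_ug_ml, fallback=True)
    return IstdCatalog(by_class=by_class)


@dataclass
class QuantTable:
    """Lipids-by-samples concentrations with per-cell provenance.

    Units are ug per mg tissue or ug per uL plasma. Provenance values:
    measured, missing, removed, imputed.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame
    classes: pd.Series                    # lipid -> class
    unit: str = "ug/mg"
    tissue: str = ""

    def __post_init__(self):
        if self.values.shape != self.provenance.shape:
            raise ValueError("provenance shape mismatch")
        measured = self.provenance.to_numpy() == "measured"
        vals = self.values.to_numpy(float)
        if np.any(measured & (vals < 0)):
            raise ValueError("measured concentrations must be nonnegative")

    def copy(self) -> "QuantTable":
        return QuantTable(self.values.copy(), self.provenance.copy(),
                          self.classes.copy(), self.unit, self.tissue)


def istd_quantify(table: FeatureTable, catalog: IstdCatalog,
                  sample_amount: float, extract_volume: float,
                  unit: str = "ug/mg") -> QuantTable:
    """Semi-absolute quantification against class-matched internal standards.

    conc = (area / ISTD area) x ISTD conc [ug/mL -> ug/uL] x extract volume
    [uL] / sample amount [mg or uL], per sample. Samples whose ISTD area is
    missing get the whole class/mode flagged missing in that sample.
    """
    study = table.study_areas
    feats = table.features
    analytes = feats.index[~feats["is_istd"].astype(bool)
                           & feats["lipid_class"].notna()]
    # locate each ISTD's area row in this table by feature name
    name_to_fid = {feats.loc[f, "name"]: f for f in feats.index
                   if feats.loc[f, "is_istd"]}
    values = pd.DataFrame(np.nan, index=analytes, columns=study.columns)
    prov = pd.DataFrame("missing", index=analytes, columns=study.columns)
    classes = feats.loc[analytes, "lipid_class"]
    for cls in classes.unique():
        entry = catalog.entry(cls)
        fid = name_to_fid.get(entry.istd_name)
        if fid is None:
            raise KeyError(
                f"ISTD {entry.istd_name!r} for class {cls!r} absent from table")
        istd_area = study.loc[fid]
        members = classes.index[classes == cls]
        ratio = study.loc[members].div(istd_area, axis=1)
        conc = (ratio * (entry.conc_ug_ml / 1000.0) * extract_volume
                / sample_amount)
        values.loc[members] = conc
        ok = np.isfinite(conc.to_numpy())
        prov.loc[members] = np.where(ok, "measured", "missing")
    return QuantTable(values=values, provenance=prov, classes=classes,
                      unit=unit, tissue=table.tissue)


def mad_class_filter(quant: QuantTable, mad_mult: float = 5.0,
                     special: Optional[Mapping[str, float]] = None):
    """Remove whole lipid classes from samples with outlying class sums.

    Per class: compute each sample's class-sum; samples deviating from the
    median by more than ``mad_mult`` times the (unscaled) MAD lose all class
    members in that sample. A zero MAD with any nonzero deviation marks the
    deviating samples as outliers. ``special`` overrides the multiplier per
    tissue (e.g. a laxer threshold for subcutaneous white adipose).
    """
    if quant.values.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    mult = (special or {}).get(quant.tissue, mad_mult)
    out = quant.copy()
    log = []
    for cls in out.classes.unique():
        members = out.classes.index[out.classes == cls]
        sums = out.values.loc[members].sum(axis=0, skipna=True)
        med = sums.median()
        dev = (sums - med).abs()
        mad = dev.median()
        if mad == 0:
            bad = sums.index[dev > 0]
        else:
            bad = sums.index[dev > mult * mad]
        for s in bad:
            out.values.loc[members, s] = np.nan
            out.provenance.loc[members, s] = "removed"
            log.append({"tissue": quant.tissue, "lipid_class": cls,
                        "sample": s, "class_sum": sums[s], "median": med,
                        "mad": mad, "multiplier": mult})
    return out, pd.DataFrame(log)


def _nipals_pca(X: np.ndarray, rank: int, tol: float, max_iter: int):
    """Uncentered NIPALS PCA on a complete matrix; returns (T, P)."""
    R = X.copy()
    n, m = X.shape
    T = np.zeros((n, rank))
    P = np.zeros((m, rank))
    for k in range(rank):
        j = int(np.argmax(np.var(R, axis=0)))
        t = R[:, j].copy()
        if not np.any(t):
            t = np.ones(n)
        for _ in range(max_iter):
            p = R.T @ t / (t @ t)
            norm = np.linalg.norm(p)
            if norm == 0:
                break
            p /= norm
            t_new = R @ p
            if np.linalg.norm(t_new - t) < tol * max(1.0, np.linalg.norm(t)):
                t = t_new
                break
            t = t_new
        T[:, k] = t
        P[:, k] = p
        R = R - np.outer(t, p)
    return T, P


def nipals_impute(data, rank: int = 2, tol: float = 1e-9,
                  max_iter: int = 500, nonnegative: bool = True):
    """Fill missing cells from a rank-``rank`` NIPALS-PCA reconstruction.

    Missing cells are initialized at the feature mean, then refined by
    alternating a NIPALS principal-component fit of the completed matrix
    with re-filling of the missing cells from the rank-``rank``
    reconstruction, until the fills stabilize. On the concentration scale
    (``nonnegative=True``) negative fills are replaced by the feature's
    observed mean; pass ``nonnegative=False`` for data on a signed (log)
    scale. Observed cells are never touched. Accepts a :class:`QuantTable`
    (returns one, provenance updated) or a DataFrame.
    """
    is_qt = isinstance(data, QuantTable)
    values = data.values if is_qt else data
    X = values.to_numpy(float)
    obs = np.isfinite(X)
    miss_frac = 1.0 - obs.mean(axis=1)
    if np.any(miss_frac >= 0.5):
        bad = values.index[miss_frac >= 0.5][:3].to_list()
        raise ValueError(f"features with >= 50% missing values: {bad} ...")
    if obs.all():
        return data.copy() if is_qt else values.copy()

    feat_mean = np.nanmean(np.where(obs, X, np.nan), axis=1)
    filled = np.where(obs, X, feat_mean[:, None])
    scale = np.nanmax(np.abs(X[obs])) or 1.0
    converged = False
    for _ in range(max_iter):
        T, P = _nipals_pca(filled, rank, tol=1e-10, max_iter=200)
        recon = T @ P.T
        new = np.where(obs, X, recon)
        delta = np.max(np.abs(new - filled))
        filled = new
        if delta < tol * scale:
            converged = True
            break
    fills = filled.copy()
    if not converged:
        fills = np.where(obs, X, feat_mean[:, None])
    neg_fill = (~obs) & (fills < 0) & nonnegative
    if neg_fill.any():
        fills = np.where(neg_fill, feat_mean[:, None] * np.ones_like(fills),
                         fills)
    out_vals = pd.DataFrame(fills, index=values.index, columns=values.columns)
    out_vals.attrs["nipals_converged"] = converged
    if not is_qt:
        return out_vals
    out = data.copy()
    out.values = out_vals
    prov = out.provenance.to_numpy(object).copy()
    prov[~obs] = "imputed"
    out.provenance = pd.DataFrame(prov, index=values.index,
                                  columns=values.columns)
    return out


def class_composition(quant: QuantTable):
    """Per-sample class sums and fractions (fractions sum to 1)."""
    sums = quant.values.groupby(quant.classes).sum(min_count=1)
    totals = sums.sum(axis=0, skipna=True)
    fractions = sums.div(totals, axis=1)
    return sums, fractions


def pcpe_ratio(quant: QuantTable) -> pd.Series:
    """Summed PC over summed PE concentration per sample (ether classes
    excluded; a zero PE sum yields NaN)."""
    cls = quant.classes
    pc = quant.values.loc[cls.index[cls == "PC"]].sum(axis=0, skipna=True)
    pe = quant.values.loc[cls.index[cls == "PE"]].sum(axis=0, skipna=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = pc / pe.replace(0.0, np.nan)
    ratio.name = "pc_pe_ratio"
    return ratio


def dha_ara_ratio(quant: QuantTable,
                  annotations: Sequence[LipidAnnotation],
                  classes: Sequence[str] = ("PC", "PE")) -> pd.DataFrame:
    """DHA:ARA ratio per sample and class.

    For each class, the ratio of summed concentrations of 22:6-containing
    over 20:4-containing chain-resolved species (each requiring a
    16:0/16:1/18:0/18:1 anchor chain). An empty ARA selection yields NaN for
    that class.
    """
    rows = {}
    for cls in classes:
        dha = select_pufa_species(annotations, [cls],
                                  target_chains=[DHA_CHAIN]).selected
        ara = select_pufa_species(annotations, [cls],
                                  target_chains=[ARA_CHAIN]).selected
        dha = [i for i in dha if i in quant.values.index]
        ara = [i for i in ara if i in quant.values.index]
        if not ara:
            rows[cls] = pd.Series(np.nan, index=quant.values.columns)
            continue
        num = quant.values.loc[dha].sum(axis=0, skipna=True)
        den = quant.values.loc[ara].sum(axis=0, skipna=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            rows[cls] = num / den.replace(0.0, np.nan)
    return pd.DataFrame(rows)


@dataclass
class CalibrationResult:
    slope: float
    intercept: float
    r_squared: float
    calibrated: bool
    concentrations: Optional[pd.Series] = None
    floored: list = field(default_factory=list)


def calibrate_targeted(standards: Sequence[tuple[float, float]],
                       unknowns: Mapping[str, float] | pd.Series,
                       r2_min: float = 0.9) -> CalibrationResult:
    """Back-calculate concentrations from an external standard curve.

    Fits area = a·conc + b by OLS over the calibration points; the curve is
    rejected (analyte uncalibrated) when R² falls below ``r2_min``. Negative
    back-calculations are floored at 0 and flagged.
    """
    pts = np.asarray(standards, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 calibration points")
    conc, area = pts[:, 0], pts[:, 1]
    slope, intercept = np.polyfit(conc, area, 1)
    fit = slope * conc + intercept
    ss_res = float(np.sum((area - fit) ** 2))
    ss_tot = float(np.sum((area - area.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if r2 < r2_min or slope <= 0:
        return CalibrationResult(slope, intercept, r2, calibrated=False)
    unknowns = pd.Series(unknowns, dtype=float)
    back = (unknowns - intercept) / slope
    floored = list(back.index[back < 0])
    back = back.clip(lower=0.0)
    return CalibrationResult(slope, intercept, r2, calibrated=True,
                             concentrations=back, floored=floored)
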