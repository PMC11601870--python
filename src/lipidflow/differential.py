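"""Moderated linear-model differential analysis.

Per-lipid ordinary least squares with a shared design matrix, followed by
empirical-Bayes shrinkage of the residual variances toward a common prior:
the residual variances :math:`s_g^2` are modelled as scaled chi-square draws
around a prior variance :math:`s_0^2` with :math:`d_0` prior degrees of
freedom, estimated by method of moments on :math:`\\log s_g^2` using
digamma/trigamma identities. The posterior variance

.. math:: \\tilde s_g^2 = \\frac{d_0 s_0^2 + d_g s_g^2}{d_0 + d_g}

replaces :math:`s_g^2` in the usual t statistic, which then has
:math:`d_0 + d_g` degrees of freedom; an F statistic over a set of contrasts
is the mean of squared moderated t statistics over an orthogonalized version
of the set.

The module is organised statsmodels-style: build a
:class:`ModeratedLinearModel` from a lipids-by-samples matrix and a design,
call :meth:`~ModeratedLinearModel.fit`, then ask the returned
:class:`ModeratedResults` for contrasts, F-tests and a summary table.
Convenience drivers cover the study's standard contrast families: the
overall-training F-test, per-timepoint contrasts against sex-matched
sedentary controls, and the two sex-contrast families (naive per-timepoint
sex differences and difference-of-differences interactions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModerationPrior",
    "ModeratedLinearModel",
    "ModeratedResults",
    "build_means_design",
    "build_mean_reference_design",
    "estimate_prior",
    "bh_adjust",
    "significant",
    "timewise_results",
    "training_f_results",
    "sex_contrast_results",
    "TIMEPOINTS",
]

TIMEPOINTS = ("1w", "2w", "4w", "8w")
REFERENCE_GROUP = "SED"


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-tolerant)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def significant(result: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Rows selected at the given BH FDR threshold."""
    return result[result["adj_p"] < fdr]


def build_means_design(groups: Sequence[str],
                       levels: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Cell-means design (one indicator per group, no intercept)."""
    groups = pd.Series(list(groups))
    if levels is None:
        levels = list(dict.fromkeys(groups))
    X = pd.DataFrame({lev: (groups == lev).astype(float) for lev in levels})
    X.index = range(len(groups))
    return X


def build_mean_reference_design(
    groups: Sequence[str], reference: str = REFERENCE_GROUP,
    levels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Intercept + non-reference indicators (mean-reference coding)."""
    groups = pd.Series(list(groups))
    if levels is None:
        levels = [g for g in dict.fromkeys(groups) if g != reference]
    else:
        levels = [g for g in levels if g != reference]
    X = pd.DataFrame({"Intercept": np.ones(len(groups))})
    for lev in levels:
        X[lev] = (groups == lev).astype(float)
    return X


@dataclass(frozen=True)
class ModerationPrior:
    """Empirical-Bayes variance prior: d0 degrees of freedom, s0² variance."""

    d0: float
    s02: float

    def __post_init__(self):
        if not (self.d0 > 0):  # +inf allowed
            raise ValueError("d0 must be positive (or +inf)")
        if not (self.s02 > 0):
            raise ValueError("s0^2 must be positive")

    def posterior_var(self, s2: np.ndarray, df: float) -> np.ndarray:
        if np.isinf(self.d0):
            return np.full_like(np.asarray(s2, float), self.s02)
        return (self.d0 * self.s02 + df * s2) / (self.d0 + df)

    @property
    def is_degenerate(self) -> bool:
        return np.isinf(self.d0)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (trigamma is strictly decreasing)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    return brentq(lambda x: special.polygamma(1, x) - y, 1e-9, 1e9,
                  xtol=1e-12, rtol=1e-12)


def estimate_prior(s2: np.ndarray, df: float, min_lipids: int = 10) -> ModerationPrior:
    """Method-of-moments fit of the scaled chi-square variance prior.

    Works on ``log s²``: with ``z = log s² − digamma(df/2) + log(df/2)``,
    ``var(z) − trigamma(df/2)`` estimates ``trigamma(d0/2)``; a non-positive
    excess variance means the variances are no more dispersed than sampling
    noise alone and the prior degenerates to ``d0 = +inf``.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < min_lipids:
        raise ValueError(f"need >= {min_lipids} positive residual variances")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return ModerationPrior(d0=d0, s02=s02)


def _t_sf(x: np.ndarray, df: float) -> np.ndarray:
    if np.isinf(df):
        return stats.norm.sf(x)
    return stats.t.sf(x, df)


def _f_sf(x: np.ndarray, k: int, df: float) -> np.ndarray:
    if np.isinf(df):
        return stats.chi2.sf(np.asarray(x) * k, k)
    return stats.f.sf(x, k, df)


class ModeratedLinearModel:
    """Shared-design OLS over a lipids-by-samples matrix.

    Parameters
    ----------
    endog : DataFrame
        Lipids (rows) by samples (columns) of normalized log2 abundances.
    design : DataFrame
        Samples by coefficients indicator matrix; rows must align with the
        columns of ``endog``.
    """

    def __init__(self, endog: pd.DataFrame, design: pd.DataFrame):
        if design.shape[0] != endog.shape[1]:
            raise ValueError("design rows must match endog columns")
        X = np.asarray(design, dtype=float)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            aliased = self._aliased_columns(X, list(design.columns))
            raise ValueError(
                f"design matrix is rank deficient (rank {rank} < "
                f"{X.shape[1]}); aliased columns: {aliased}")
        self.endog = endog
        self.design = design
        self._X = X

    @staticmethod
    def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        tol = diag.max() * 1e-8 if diag.size else 0.0
        return [names[j] for j in range(len(names)) if diag[j] <= tol]

    @classmethod
    def from_dataframe(cls, matrix: pd.DataFrame, meta: pd.DataFrame,
                       group_col: str = "group",
                       coding: str = "means",
                       reference: str = REFERENCE_GROUP,
                       levels: Optional[Sequence[str]] = None):
        """Build from a matrix plus per-sample metadata.

        ``meta`` is indexed by (or contains a column matching) the matrix's
        sample columns; ``coding`` is ``"means"`` (no intercept) or
        ``"mean_reference"`` (intercept + non-reference indicators).
        """
        groups = meta.loc[list(matrix.columns), group_col]
        if coding == "means":
            design = build_means_design(groups, levels=levels)
        elif coding == "mean_reference":
            design = build_mean_reference_design(groups, reference=reference,
                                                 levels=levels)
        else:
            raise ValueError("coding must be 'means' or 'mean_reference'")
        design.index = matrix.columns
        return cls(matrix, design)

    def fit(self, moderate: bool = True,
            prior: Optional[ModerationPrior] = None) -> "ModeratedResults":
        X = self._X
        Y = np.asarray(self.endog, dtype=float)
        n, p = X.shape
        df_resid = n - p
        if df_resid < 1:
            raise ValueError("residual degrees of freedom must be >= 1")
        XtX = X.T @ X
        XtX_inv = np.linalg.inv(XtX)
        coef = Y @ X @ XtX_inv.T              # lipids x p
        resid = Y - coef @ X.T
        s2 = np.einsum("ij,ij->i", resid, resid) / df_resid
        if prior is None and moderate:
            prior = estimate_prior(s2, df_resid)
        return ModeratedResults(self, coef, s2, df_resid, XtX_inv, prior)


class ModeratedResults:
    """Fitted coefficients plus the shrinkage prior; produces contrast tables."""

    def __init__(self, model: ModeratedLinearModel, coef: np.ndarray,
                 s2: np.ndarray, df_resid: int, XtX_inv: np.ndarray,
                 prior: Optional[ModerationPrior]):
        self.model = model
        self.coef = pd.DataFrame(coef, index=model.endog.index,
                                 columns=model.design.columns)
        self.s2 = pd.Series(s2, index=model.endog.index, name="s2")
        self.df_resid = df_resid
        self.XtX_inv = XtX_inv
        self.prior = prior

    # -- internals ---------------------------------------------------------
    @property
    def _d0(self) -> float:
        return self.prior.d0 if self.prior is not None else 0.0

    @property
    def _df_total(self) -> float:
        return self.df_resid + self._d0

    def _posterior_var(self) -> np.ndarray:
        s2 = self.s2.to_numpy()
        if self.prior is None:
            return s2
        return self.prior.posterior_var(s2, self.df_resid)

    def _contrast_vector(self, contrast) -> np.ndarray:
        cols = list(self.model.design.columns)
        if isinstance(contrast, Mapping):
            c = np.zeros(len(cols))
            for name, w in contrast.items():
                c[cols.index(name)] = w
            return c
        c = np.asarray(contrast, dtype=float)
        if c.shape != (len(cols),):
            raise ValueError("contrast length must match design columns")
        return c

    # -- public API --------------------------------------------------------
    def contrast(self, contrast, name: str = "contrast") -> pd.DataFrame:
        """Moderated t-test of a single contrast.

        Returns a DataFrame with columns lipid, logFC (the contrast of
        coefficient estimates, i.e. a difference of group means under means
        coding), t, p, adj_p, contrast.
        """
        c = self._contrast_vector(contrast)
        cb = self.coef.to_numpy() @ c
        cvc = float(c @ self.XtX_inv @ c)
        if cvc <= 0:
            raise ValueError("contrast has zero variance under the design")
        s2p = self._posterior_var()
        t = cb / np.sqrt(s2p * cvc)
        p = 2.0 * _t_sf(np.abs(t), self._df_total)
        return pd.DataFrame({
            "lipid": self.model.endog.index,
            "logFC": cb,
            "t": t,
            "p": p,
            "adj_p": bh_adjust(p),
            "contrast": name,
        }).set_index("lipid")

    def f_test(self, contrasts: Sequence, name: str = "F") -> pd.DataFrame:
        """Moderated F-test over a set of linearly independent contrasts.

        Equivalent to the mean of squared moderated t statistics over an
        orthogonalized version of the contrast set; with a single contrast
        this is exactly t².
        """
        C = np.column_stack([self._contrast_vector(c) for c in contrasts])
        k = C.shape[1]
        U = C.T @ self.XtX_inv @ C              # covariance (unit variance)
        if np.linalg.matrix_rank(U) < k:
            raise ValueError("contrasts are linearly dependent")
        B = self.coef.to_numpy() @ C            # lipids x k
        Uinv = np.linalg.inv(U)
        quad = np.einsum("ij,jk,ik->i", B, Uinv, B)
        s2p = self._posterior_var()
        F = quad / (k * s2p)
        p = _f_sf(F, k, self._df_total)
        return pd.DataFrame({
            "lipid": self.model.endog.index,
            "F": F,
            "p": p,
            "adj_p": bh_adjust(p),
            "contrast": name,
        }).set_index("lipid")

    def summary(self, top: int = 10) -> str:
        lines = [
            "Moderated linear model results",
            "=" * 46,
            f"lipids:              {self.coef.shape[0]}",
            f"samples:             {self.model.design.shape[0]}",
            f"coefficients:        {list(self.coef.columns)}",
            f"residual df:         {self.df_resid}",
        ]
        if self.prior is not None:
            d0 = self.prior.d0
            lines += [
                f"prior df (d0):       {'inf' if np.isinf(d0) else f'{d0:.3f}'}",
                f"prior var (s0^2):    {self.prior.s02:.5f}",
            ]
        else:
            lines.append("prior:               none (ordinary OLS t)")
        lines.append("-" * 46)
        lines.append("largest residual variances:")
        for lip, v in self.s2.sort_values(ascending=False).head(top).items():
            lines.append(f"  {lip}: s2={v:.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Study-standard contrast families
# ---------------------------------------------------------------------------

def timewise_results(matrix: pd.DataFrame, meta: pd.DataFrame,
                     timepoints: Sequence[str] = TIMEPOINTS,
                     reference: str = REFERENCE_GROUP,
                     moderate: bool = True) -> pd.DataFrame:
    """Per-timepoint contrasts vs the reference group (means coding).

    One model fit shared across lipids; BH adjustment is applied within each
    timepoint contrast. The logFC is exactly the difference of cell means.
    """
    levels = [reference] + [t for t in timepoints]
    model = ModeratedLinearModel.from_dataframe(
        matrix, meta, coding="means", levels=levels)
    res = model.fit(moderate=moderate)
    frames = []
    for tp in timepoints:
        tab = res.contrast({tp: 1.0, reference: -1.0}, name=f"{tp}_vs_{reference}")
        tab["timepoint"] = tp
        frames.append(tab.reset_index())
    return pd.concat(frames, ignore_index=True)


def training_f_results(matrix: pd.DataFrame, meta: pd.DataFrame,
                       timepoints: Sequence[str] = TIMEPOINTS,
                       reference: str = REFERENCE_GROUP,
                       moderate: bool = True) -> pd.DataFrame:
    """Overall-training moderated F-test combining all timepoint contrasts."""
    levels = [reference] + list(timepoints)
    model = ModeratedLinearModel.from_dataframe(
        matrix, meta, coding="means", levels=levels)
    res = model.fit(moderate=moderate)
    contrasts = [{tp: 1.0, reference: -1.0} for tp in timepoints]
    return res.f_test(contrasts, name="training_F").reset_index()


def sex_contrast_results(matrix: pd.DataFrame, meta: pd.DataFrame,
                         timepoints: Sequence[str] = TIMEPOINTS,
                         reference: str = REFERENCE_GROUP,
                         sexes: Sequence[str] = ("male", "female"),
                         moderate: bool = True) -> pd.DataFrame:
    """Both sex-contrast families from a joint two-sex cell-means fit.

    Emits, per timepoint (including the reference for the naive family):

    * ``naive``: male minus female at the same group, e.g. male SED − female
      SED;
    * ``interaction``: the sex-dimorphic training response, (male tp − male
      ref) − (female tp − female ref).

    Cells absent from the data skip their contrasts (recorded in the
    ``skipped`` attribute of the returned frame).
    """
    cells = meta.loc[list(matrix.columns)]
    cell_label = cells["sex"].astype(str) + ":" + cells["group"].astype(str)
    present = set(cell_label)
    levels = [f"{s}:{g}" for s in sexes for g in [reference, *timepoints]
              if f"{s}:{g}" in present]
    meta2 = meta.copy()
    meta2["cell"] = meta2["sex"].astype(str) + ":" + meta2["group"].astype(str)
    model = ModeratedLinearModel.from_dataframe(
        matrix, meta2, group_col="cell", coding="means", levels=levels)
    res = model.fit(moderate=moderate)
    male, female = sexes
    frames, skipped = [], []
    for tp in [reference, *timepoints]:
        a, b = f"{male}:{tp}", f"{female}:{tp}"
        if a in levels and b in levels:
            tab = res.contrast({a: 1.0, b: -1.0}, name=f"naive_{tp}")
            tab["timepoint"] = tp
            tab["family"] = "naive"
            frames.append(tab.reset_index())
        else:
            skipped.append(f"naive_{tp}")
    mr, fr = f"{male}:{reference}", f"{female}:{reference}"
    for tp in timepoints:
        a, b = f"{male}:{tp}", f"{female}:{tp}"
        if all(lv in levels for lv in (a, b, mr, fr)):
            tab = res.contrast({a: 1.0, mr: -1.0, b: -1.0, fr: 1.0},
                               name=f"interaction_{tp}")
            tab["timepoint"] = tp
            tab["family"] = "interaction"
            frames.append(tab.reset_index())
        else:
            skipped.append(f"interaction_{tp}")
    out = pd.concat(frames, ignore_index=True)
    out.attrs["skipped"] = skipped
    return out
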