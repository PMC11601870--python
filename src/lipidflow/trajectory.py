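"""Fuzzy c-means clustering of time courses and logFC trajectory correlations.

Lipid time courses are the z-scored group (sex-by-timepoint) means of the
normalized data. Fuzzy c-means with fuzzifier m alternates the membership
update ``u_ik = 1 / sum_j (d_ik / d_jk)^(2/(m-1))`` with weighted centroid
recomputation; the objective ``sum u^m d^2`` is nonincreasing. A lipid
belongs to a cluster's core when its membership reaches 0.5 — at most one
core per lipid since memberships are row-stochastic. The cluster count is
chosen from the minimum pairwise centroid distance curve by its elbow
(maximum concave curvature), with the curve returned for visual override.

Sex- and tissue-concordance of training responses uses the 5-point Pearson
correlation of each lipid's logFC trajectory (0 at baseline, then the four
timewise logFCs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "build_trajectory_matrix",
    "FuzzyCMeans",
    "ClusterResult",
    "choose_c",
    "ElbowResult",
    "logfc_trajectories",
    "trajectory_correlation",
    "pairwise_trajectory_correlations",
    "correlation_density_summary",
]


def build_trajectory_matrix(matrix: pd.DataFrame, meta: pd.DataFrame,
                            by: Sequence[str] = ("sex", "group")) -> pd.DataFrame:
    """Z-scored group means: lipids x (sex, timepoint) cells, each row mean 0
    and (population) sd 1."""
    cells = meta.loc[list(matrix.columns), list(by)]
    labels = pd.MultiIndex.from_frame(cells)
    means = matrix.T.groupby(labels).mean().T
    z = means.sub(means.mean(axis=1), axis=0)
    sd = z.std(axis=1, ddof=0)
    return z.div(sd.replace(0.0, np.nan), axis=0).dropna(how="any")


@dataclass
class ClusterResult:
    centroids: pd.DataFrame          # c x features
    membership: pd.DataFrame         # lipids x c, rows sum to 1
    m: float
    objective_path: list
    core_threshold: float = 0.5

    @property
    def core(self) -> pd.Series:
        """Core cluster per lipid (membership >= threshold), else -1."""
        u = self.membership
        best = u.idxmax(axis=1)
        top = u.max(axis=1)
        return best.where(top >= self.core_threshold, other=-1)

    def core_members(self, cluster) -> list:
        core = self.core
        return list(core.index[core == cluster])

    def hard_labels(self) -> pd.Series:
        return self.membership.idxmax(axis=1)

    def plot(self, ax=None):
        """Line plot of core-member trajectories per cluster."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for c in self.centroids.index:
            ax.plot(range(self.centroids.shape[1]),
                    self.centroids.loc[c], label=f"cluster {c}")
        ax.set_xlabel("trajectory point")
        ax.set_ylabel("standardized abundance")
        ax.legend()
        return ax


class FuzzyCMeans:
    """Fuzzy c-means estimator (scikit-learn-flavoured fit interface).

    Parameters: ``n_clusters``, fuzzifier ``m`` (> 1; 1.5 by default —
    m -> 1 approaches hard k-means), convergence tolerance on centroid
    movement, restart count (best objective kept) and seed. Centroids are
    initialized k-means++-style.
    """

    def __init__(self, n_clusters: int, m: float = 1.5, tol: float = 1e-6,
                 max_iter: int = 300, n_init: int = 10,
                 seed: Optional[int] = None):
        if n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.seed = seed

    def _init_centroids(self, X: np.ndarray, rng) -> np.ndarray:
        n = X.shape[0]
        idx = [int(rng.integers(n))]
        for _ in range(self.n_clusters - 1):
            d2 = np.min(((X[:, None, :] - X[idx][None, :, :]) ** 2).sum(-1),
                        axis=1)
            total = d2.sum()
            if total == 0:
                idx.append(int(rng.integers(n)))
            else:
                idx.append(int(rng.choice(n, p=d2 / total)))
        return X[idx].copy()

    def _memberships(self, X: np.ndarray, C: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(-1)
        zero = d2 <= 1e-300
        expo = 1.0 / (self.m - 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-expo)
            u = inv / inv.sum(axis=1, keepdims=True)
        # a point coincident with a centroid belongs there with membership 1
        rows = zero.any(axis=1)
        if rows.any():
            u[rows] = 0.0
            u[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
        return u

    def fit(self, data: pd.DataFrame) -> ClusterResult:
        X = np.asarray(data, dtype=float)
        rng = np.random.default_rng(self.seed)
        best = None
        for _ in range(self.n_init):
            C = self._init_centroids(X, rng)
            path = []
            for _ in range(self.max_iter):
                u = self._memberships(X, C)
                um = u ** self.m
                d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(-1)
                path.append(float((um * d2).sum()))
                C_new = (um.T @ X) / um.sum(axis=0)[:, None]
                shift = np.sqrt(((C_new - C) ** 2).sum(-1)).max()
                C = C_new
                if shift < self.tol:
                    break
            u = self._memberships(X, C)
            um = u ** self.m
            d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(-1)
            obj = float((um * d2).sum())
            path.append(obj)
            if best is None or obj < best[0]:
                best = (obj, C, u, path)
        _, C, u, path = best
        centroids = pd.DataFrame(C, index=range(self.n_clusters),
                                 columns=data.columns)
        membership = pd.DataFrame(u, index=data.index,
                                  columns=range(self.n_clusters))
        return ClusterResult(centroids=centroids, membership=membership,
                             m=self.m, objective_path=path)


@dataclass
class ElbowResult:
    chosen_c: int
    min_centroid_distance: pd.Series
    curvature: pd.Series
    low_confidence: bool


def choose_c(data: pd.DataFrame, c_range: Sequence[int], m: float = 1.5,
             seed: Optional[int] = None, n_init: int = 3) -> ElbowResult:
    """Pick the cluster count from the minimum-centroid-distance curve.

    For each candidate c the minimum pairwise centroid distance is computed;
    the elbow is the interior c with the largest concave curvature
    ``2 d(c) − d(c−1) − d(c+1)`` (the point after which adding clusters
    stops separating them). A flat curve (curvature small relative to the
    distance scale) flags the choice as low-confidence; the full curve is
    returned so a caller can override visually.
    """
    cs = sorted(set(int(c) for c in c_range))
    if any(c < 2 or c > len(data) - 1 for c in cs):
        raise ValueError("c_range must lie within [2, n_lipids - 1]")
    dmin = {}
    for c in cs:
        res = FuzzyCMeans(c, m=m, seed=seed, n_init=n_init).fit(data)
        C = res.centroids.to_numpy()
        dists = np.sqrt(((C[:, None, :] - C[None, :, :]) ** 2).sum(-1))
        iu = np.triu_indices(c, 1)
        dmin[c] = float(dists[iu].min())
    curve = pd.Series(dmin)
    if len(cs) < 3:
        return ElbowResult(chosen_c=cs[0], min_centroid_distance=curve,
                           curvature=pd.Series(dtype=float),
                           low_confidence=True)
    curv = pd.Series({cs[i]: 2 * curve[cs[i]] - curve[cs[i - 1]] - curve[cs[i + 1]]
                      for i in range(1, len(cs) - 1)})
    chosen = int(curv.idxmax())
    # knee strength relative to the spread of the data: structureless input
    # yields centroid-distance wiggles far smaller than the point norms
    X = np.asarray(data, float)
    scale = float(np.median(np.linalg.norm(X - X.mean(0), axis=1)))
    low = scale <= 0 or curv.max() < 0.25 * scale
    return ElbowResult(chosen_c=chosen, min_centroid_distance=curve,
                       curvature=curv, low_confidence=bool(low))


def logfc_trajectories(timewise: pd.DataFrame,
                       timepoints: Sequence[str] = ("1w", "2w", "4w", "8w")
                       ) -> pd.DataFrame:
    """Lipids x 5 logFC trajectories with the prepended 0 baseline."""
    wide = timewise.pivot_table(index="lipid", columns="timepoint",
                                values="logFC")
    wide = wide[list(timepoints)]
    out = pd.concat([pd.Series(0.0, index=wide.index, name="baseline"), wide],
                    axis=1)
    return out


def trajectory_correlation(a: Sequence[float], b: Sequence[float]) -> float:
    """Pearson r of two aligned 5-point logFC trajectories.

    Both must start at the 0 baseline; a zero-variance trajectory yields NaN
    (flagged missing, not zero correlation).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("trajectories must be aligned 1-d vectors")
    if a[0] != 0.0 or b[0] != 0.0:
        raise ValueError("trajectories must start at the 0 baseline")
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def pairwise_trajectory_correlations(traj_a: pd.DataFrame,
                                     traj_b: pd.DataFrame) -> pd.Series:
    """Per-lipid trajectory correlation over the lipids shared by two units
    (sexes or tissues)."""
    shared = traj_a.index.intersection(traj_b.index)
    out = {}
    for lip in shared:
        out[lip] = trajectory_correlation(traj_a.loc[lip].to_numpy(),
                                          traj_b.loc[lip].to_numpy())
    return pd.Series(out, dtype=float, name="r")


def correlation_density_summary(r_values: pd.DataFrame,
                                group_keys: Sequence[str],
                                bins: int = 40):
    """Per-group median correlation plus binned density export.

    ``r_values`` is long format with an ``r`` column and grouping columns;
    returns (medians Series, densities dict group -> (bin_edges, counts)).
    """
    finite = r_values[np.isfinite(r_values["r"])]
    if finite.empty:
        raise ValueError("no finite correlations to summarize")
    grouped = finite.groupby(list(group_keys))["r"]
    medians = grouped.median()
    edges = np.linspace(-1, 1, bins + 1)
    densities = {key: np.histogram(vals, bins=edges, density=True)[0]
                 for key, vals in grouped}
    return medians, {"edges": edges, "counts": densities}
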