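"""Cross-tissue correlation networks and signed-TOM co-expression modules.

Two complementary views of lipid co-regulation:

* **Sample-level correlation networks** — all pairwise Pearson correlations
  between (tissue, lipid) nodes over animals matched across tissues, with
  Bonferroni control over every tested pair; edges split into intra- and
  inter-tissue scopes with degree and tissue-pair summaries.

* **Weighted co-expression modules** — within a tissue, a signed soft
  adjacency ``a = ((1 + r) / 2)^beta`` is turned into the topological
  overlap matrix (TOM), lipids are average-linkage clustered on 1 − TOM,
  the tree is cut at the height maximizing weighted modularity, small
  modules fall into a grey pool, and modules with near-identical
  eigen-profiles (first principal component of the module's standardized
  submatrix) are merged. Module membership kME is a lipid's correlation
  with the eigen-profile; lipids with |kME| >= 0.7 are the module's hubs.
  Eigen-profiles correlate against phenotypes per sex to planted or
  measured physiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, cut_tree
from scipy.spatial.distance import squareform

__all__ = [
    "NetworkGraph",
    "ModuleSet",
    "build_correlation_network",
    "tom_similarity",
    "detect_modules",
    "membership_scores",
    "module_phenotype_correlation",
]


def _corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r at sample size n (t transform)."""
    r = np.clip(r, -0.9999999999, 0.9999999999)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return 2.0 * stats.t.sf(np.abs(t), n - 2)


@dataclass
class NetworkGraph:
    """Undirected thresholded correlation network over (tissue, lipid) nodes."""

    nodes: pd.DataFrame                 # index node id; columns tissue, lipid
    edges: pd.DataFrame                 # node_a, node_b, r, p, adj_p, sign, scope
    n_samples: int
    n_tested: int
    n_skipped: int = 0
    alpha: float = 0.05

    def degree(self) -> pd.Series:
        counts = pd.concat([self.edges["node_a"],
                            self.edges["node_b"]]).value_counts()
        return counts.reindex(self.nodes.index, fill_value=0)

    def subgraph(self, scope: str) -> pd.DataFrame:
        return self.edges[self.edges["scope"] == scope]

    def tissue_pair_counts(self) -> pd.DataFrame:
        e = self.edges.copy()
        ta = self.nodes.loc[e["node_a"], "tissue"].to_numpy()
        tb = self.nodes.loc[e["node_b"], "tissue"].to_numpy()
        pair = [tuple(sorted(p)) for p in zip(ta, tb)]
        e["tissue_pair"] = pair
        return (e.groupby(["tissue_pair", "sign"]).size()
                .rename("n_edges").reset_index())

    def to_networkx(self):
        import networkx as nx
        g = nx.Graph()
        for nid, row in self.nodes.iterrows():
            g.add_node(nid, tissue=row["tissue"], lipid=row["lipid"])
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.node_a, row.node_b, r=row.r, adj_p=row.adj_p,
                       sign=row.sign, scope=row.scope)
        return g

    def summary(self) -> str:
        intra = (self.edges["scope"] == "intra").sum()
        inter = (self.edges["scope"] == "inter").sum()
        return (f"NetworkGraph: {len(self.nodes)} nodes, "
                f"{len(self.edges)} edges ({intra} intra, {inter} inter) "
                f"at Bonferroni-adjusted p < {self.alpha} over "
                f"{self.n_tested} tested pairs")


def build_correlation_network(matrices: Mapping[str, pd.DataFrame],
                              alpha: float = 0.05,
                              min_samples: int = 4) -> NetworkGraph:
    """All-pairs Pearson network over animal-matched tissue matrices.

    ``matrices`` maps tissue -> lipids x animals normalized data (one sex);
    animals are matched across tissues by column id and reduced to the
    common set. Every lipid pair (within and between tissues) is tested;
    p-values are Bonferroni-corrected over all tested pairs and edges kept
    at adjusted p < alpha. Pairs with fewer than ``min_samples`` mutually
    observed animals are skipped and counted.
    """
    common = None
    for mat in matrices.values():
        cols = set(mat.columns)
        common = cols if common is None else (common & cols)
    common = sorted(common or [])
    if len(common) < min_samples:
        raise ValueError(f"need >= {min_samples} matched animals across tissues")

    blocks, node_rows = [], []
    for tissue in sorted(matrices):
        mat = matrices[tissue][common]
        blocks.append(mat.to_numpy(float))
        for lip in mat.index:
            node_rows.append({"node": f"{tissue}::{lip}", "tissue": tissue,
                              "lipid": lip})
    nodes = pd.DataFrame(node_rows).set_index("node")
    X = np.vstack(blocks)
    n = len(common)

    obs = np.isfinite(X)
    complete = obs.all(axis=1)
    n_skipped = 0
    if not complete.all():
        # incomplete rows: test only pairs with enough mutual observations
        n_skipped = int((~complete).sum())
    Xc = np.where(obs, X, np.nan)
    with np.errstate(invalid="ignore"):
        R = pd.DataFrame(Xc).T.corr().to_numpy()
    p = _corr_pvalues(R, n)
    iu = np.triu_indices(len(nodes), 1)
    pv = p[iu]
    rv = R[iu]
    ok = np.isfinite(rv)
    n_tested = int(ok.sum())
    n_skipped += int((~ok).sum())
    adj = np.minimum(pv * n_tested, 1.0)
    keep = ok & (adj < alpha)

    ia, ib = iu[0][keep], iu[1][keep]
    node_ids = nodes.index.to_numpy()
    ta = nodes["tissue"].to_numpy()
    edges = pd.DataFrame({
        "node_a": node_ids[ia],
        "node_b": node_ids[ib],
        "r": rv[keep],
        "p": pv[keep],
        "adj_p": adj[keep],
        "sign": np.where(rv[keep] >= 0, "positive", "negative"),
        "scope": np.where(ta[ia] == ta[ib], "intra", "inter"),
    })
    return NetworkGraph(nodes=nodes, edges=edges, n_samples=n,
                        n_tested=n_tested, n_skipped=n_skipped, alpha=alpha)


def tom_similarity(matrix: pd.DataFrame, beta: int = 6,
                   signed: bool = True) -> pd.DataFrame:
    """Topological overlap matrix from a soft-thresholded correlation
    adjacency.

    Signed adjacency ``a = ((1 + r) / 2)^beta`` (or ``|r|^beta`` unsigned);
    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`` with
    connectivities k excluding the diagonal; the diagonal is set to 1.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    X = matrix.to_numpy(float)
    r = np.corrcoef(X)
    a = ((1.0 + r) / 2.0) ** beta if signed else np.abs(r) ** beta
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    L = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (L + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=matrix.index, columns=matrix.index)


def _eigenprofile(sub: pd.DataFrame) -> pd.Series:
    """First PC of the standardized module submatrix, unit norm, oriented to
    correlate positively with the module mean profile."""
    X = sub.to_numpy(float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    e = vt[0]
    mean_profile = Z.mean(axis=0)
    if np.dot(e, mean_profile) < 0:
        e = -e
    return pd.Series(e, index=sub.columns)


@dataclass
class ModuleSet:
    """Disjoint co-expression modules with eigen-profiles and hub lipids.

    Module label 0 is the grey pool of unassigned lipids.
    """

    labels: pd.Series                   # lipid -> module id (0 = grey)
    eigenprofiles: pd.DataFrame         # samples x module ids
    beta: int
    min_size: int
    kme: Optional[pd.DataFrame] = None  # lipids x module ids
    hub_threshold: float = 0.7

    @property
    def modules(self) -> dict:
        return {int(mid): list(self.labels.index[self.labels == mid])
                for mid in sorted(set(self.labels)) if mid != 0}

    def hubs(self, module: int) -> list:
        if self.kme is None:
            raise ValueError("membership scores not computed")
        members = self.labels.index[self.labels == module]
        k = self.kme.loc[members, module]
        return list(k.index[np.abs(k) >= self.hub_threshold])


def detect_modules(tom: pd.DataFrame, data: pd.DataFrame, min_size: int = 3,
                   merge_cut: float = 0.15, beta: int = 6,
                   n_cut_candidates: int = 25) -> ModuleSet:
    """Hierarchical modules on TOM dissimilarity with a modularity-scored cut.

    Average-linkage clustering on 1 − TOM; candidate cut heights over the
    merge-height range are scored by weighted modularity of the TOM graph
    and the best kept. Modules below ``min_size`` join the grey pool;
    modules whose eigen-profiles correlate above 1 − merge_cut are merged
    (largest first). Returns an empty ModuleSet (all grey) with a warning
    label when nothing passes.
    """
    if min_size < 3:
        raise ValueError("min_size must be >= 3")
    lipids = tom.index
    D = 1.0 - tom.to_numpy(float)
    np.fill_diagonal(D, 0.0)
    Z = average(squareform(D, checks=False))
    heights = Z[:, 2]
    lo, hi = float(heights.min()), float(heights.max())
    candidates = np.linspace(lo + 1e-9, hi - 1e-9,
                             num=min(n_cut_candidates, max(2, len(heights))))

    W = tom.to_numpy(float).copy()
    np.fill_diagonal(W, 0.0)
    two_m = W.sum()
    k_w = W.sum(axis=1)

    def modularity(labels: np.ndarray) -> float:
        q = 0.0
        for mid in np.unique(labels):
            mask = labels == mid
            q += (W[np.ix_(mask, mask)].sum()
                  - (k_w[mask].sum() ** 2) / two_m) / two_m
        return q

    best_labels, best_q = None, -np.inf
    for h in candidates:
        labels = cut_tree(Z, height=h).ravel()
        if len(np.unique(labels)) < 2:
            continue
        q = modularity(labels)
        if q > best_q:
            best_q, best_labels = q, labels
    if best_labels is None:
        best_labels = np.zeros(len(lipids), dtype=int)

    # relabel: size-filtered, 1-based ids in decreasing size order
    labels = pd.Series(best_labels, index=lipids)
    sizes = labels.value_counts()
    keep = [mid for mid in sizes.index if sizes[mid] >= min_size]
    keep.sort(key=lambda mid: -sizes[mid])
    relabel = {mid: i + 1 for i, mid in enumerate(keep)}
    labels = labels.map(lambda m: relabel.get(m, 0))

    # eigen-profile merge
    def profiles(lbl: pd.Series) -> pd.DataFrame:
        cols = {}
        for mid in sorted(set(lbl)):
            if mid == 0:
                continue
            cols[mid] = _eigenprofile(data.loc[lbl.index[lbl == mid]])
        return pd.DataFrame(cols)

    eig = profiles(labels)
    merged = True
    while merged and eig.shape[1] > 1:
        merged = False
        corr = eig.corr()
        np.fill_diagonal(corr.values, 0.0)
        pairs = corr.stack()
        if (pairs > 1.0 - merge_cut).any():
            (a, b) = pairs.idxmax()
            keep_id, drop_id = (a, b) if (labels == a).sum() >= (labels == b).sum() else (b, a)
            labels = labels.replace(drop_id, keep_id)
            eig = profiles(labels)
            merged = True

    # final relabel to consecutive ids by size
    sizes = labels[labels != 0].value_counts()
    relabel = {mid: i + 1 for i, mid in enumerate(sizes.index)}
    labels = labels.map(lambda m: relabel.get(m, 0))
    eig = profiles(labels)
    if eig.empty:
        eig = pd.DataFrame(index=data.columns)
    return ModuleSet(labels=labels, eigenprofiles=eig, beta=beta,
                     min_size=min_size)


def membership_scores(modules: ModuleSet, matrix: pd.DataFrame) -> pd.DataFrame:
    """kME: Pearson correlation of each lipid with each module eigen-profile.

    Stored on the ModuleSet (enabling ``hubs``); hub lipids have
    |kME| >= 0.7 for their own module.
    """
    if modules.eigenprofiles.empty:
        raise ValueError("module set has no modules")
    X = matrix.to_numpy(float)
    Xz = (X - X.mean(1, keepdims=True))
    sd = Xz.std(1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    Xz /= sd
    out = {}
    for mid in modules.eigenprofiles.columns:
        e = modules.eigenprofiles[mid].loc[matrix.columns].to_numpy(float)
        ez = (e - e.mean()) / (e.std(ddof=0) or 1.0)
        out[mid] = (Xz * ez).mean(axis=1)
    kme = pd.DataFrame(out, index=matrix.index)
    modules.kme = kme
    return kme


def module_phenotype_correlation(modules: ModuleSet, phenotypes: pd.DataFrame,
                                 alpha: float = 0.05,
                                 pairing: Optional[Mapping[int, Sequence[str]]] = None
                                 ) -> pd.DataFrame:
    """Pearson correlation of module eigen-profiles against phenotypes.

    ``phenotypes`` rows must align with the eigen-profile index (samples /
    animals, one sex). Edges are reported at raw p < alpha; ``pairing``
    optionally restricts which phenotypes are tested per module (the
    role-based pairing of storage-lipid modules with adiposity measures and
    membrane-lipid modules with fitness markers is configuration, not code).
    Constant phenotypes are skipped and flagged.
    """
    eig = modules.eigenprofiles
    common = eig.index.intersection(phenotypes.index)
    if len(common) < 3:
        raise ValueError("need >= 3 matched samples between profiles and phenotypes")
    rows, skipped = [], []
    for mid in eig.columns:
        phenos = (pairing or {}).get(mid, phenotypes.columns)
        for ph in phenos:
            y = phenotypes.loc[common, ph].astype(float)
            if y.std(ddof=0) == 0:
                skipped.append((mid, ph))
                continue
            r, p = stats.pearsonr(eig.loc[common, mid], y)
            rows.append({"module": mid, "phenotype": ph, "r": r, "p": p,
                         "significant": p < alpha})
    out = pd.DataFrame(rows)
    out.attrs["skipped_constant"] = skipped
    return out
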