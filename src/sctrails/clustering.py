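"""Two-step clustering with DE-based merging and artifact-cluster flagging.

Step one builds a shared-nearest-neighbour (SNN) graph on the log expression
of highly variable genes (k = 20, Jaccard edge weights) and applies Louvain
multi-level modularity optimisation for a coarse partition. Step two refines
each coarse cluster by average-linkage hierarchical clustering on
1 - Spearman correlation distances, choosing the number of sub-clusters by
maximising the gap statistic against uniform reference datasets.

Post-processing merges refined clusters separated by fewer than 10
differentially expressed genes (threshold test, raw p < 0.01, |log2FC| > 1),
flags clusters matching non-epithelial marker panels as contaminants, and
flags putative doublet clusters: rare (< 7% of every sample where present)
clusters whose mean log2(count+1) profile is highly correlated (Spearman
rho > 0.9) with at least two co-occurring clusters and with the arithmetic
mean of the best such pair.
"""

from __future__ import annotations

import logging
import random as _pyrandom
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Optional, Sequence

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform
from sklearn.neighbors import NearestNeighbors

from .containers import ClusterAssignment
from .diffexpr import count_de_genes

logger = logging.getLogger(__name__)

DEFAULT_CONTAMINANT_MARKERS = {
    # shipped defaults for mouse mammary tissue; fully configurable
    "immune": ["Cd74", "Cd72", "Cd54"],
    "fibroblast": ["Col1a1", "Col1a2", "Col3a1", "Fn1"],
    "endothelial": ["Eng", "S1pr1", "Emcn"],
}


@dataclass
class SNNGraph:
    """Weighted shared-nearest-neighbour graph over cells."""

    n_nodes: int
    k: int
    edges: np.ndarray       # m x 2 int array, u < v
    weights: np.ndarray     # Jaccard of the two kNN sets (self included)
    weight_kind: str = "jaccard"

    def to_igraph(self) -> igraph.Graph:
        g = igraph.Graph(n=self.n_nodes, edges=[tuple(e) for e in self.edges])
        g.es["weight"] = self.weights.tolist()
        return g


def build_snn_graph(expr: np.ndarray, k: int = 20) -> SNNGraph:
    """SNN graph: edge wherever two cells' kNN sets (self included) overlap,
    weighted by the Jaccard index of the sets. Euclidean kNN, ties broken by
    cell index."""
    X = np.asarray(expr, dtype=float)
    n = X.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} cells, got {n}")
    nn = NearestNeighbors(n_neighbors=k).fit(X)
    idx = nn.kneighbors(X, return_distance=False)
    # guarantee self-membership (exact duplicates can evict it)
    has_self = (idx == np.arange(n)[:, None]).any(axis=1)
    idx[~has_self, -1] = np.flatnonzero(~has_self)

    rows = np.repeat(np.arange(n), k)
    M = sp.csr_matrix((np.ones(n * k), (rows, idx.ravel())), shape=(n, n))
    S = (M @ M.T).tocoo()  # pairwise intersection sizes
    mask = (S.row < S.col) & (S.data > 0)
    u, v, inter = S.row[mask], S.col[mask], S.data[mask]
    jac = inter / (2 * k - inter)
    return SNNGraph(n_nodes=n, k=k, edges=np.column_stack([u, v]),
                    weights=jac)


def louvain_cluster(g: SNNGraph, seed: int = 0) -> np.ndarray:
    """Coarse labels from multi-level (Louvain) modularity optimisation."""
    graph = g.to_igraph()
    _pyrandom.seed(seed)  # igraph's python RNG
    part = graph.community_multilevel(weights="weight")
    return np.asarray(part.membership, dtype=int)


def spearman_distance(X: np.ndarray) -> np.ndarray:
    """1 - Spearman rank correlation between rows; constant rows get rho 0."""
    X = np.asarray(X, dtype=float)
    ranks = sps.rankdata(X, axis=1)
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant cells: Spearman rho set to 0", constant.sum())
    safe = ranks.copy()
    safe[constant] += np.arange(X.shape[1])  # placeholder, corrected below
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(safe)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    D = 1.0 - corr
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, None)


def _pooled_within_dispersion(D: np.ndarray, labels: np.ndarray) -> float:
    """Tibshirani's W_k: sum over clusters of within-cluster pairwise
    distances divided by twice the cluster size."""
    total = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) > 1:
            total += D[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return total


def gap_statistic(X: np.ndarray, k_max: int = 6, B: int = 50,
                  seed: int = 0) -> tuple[int, pd.DataFrame]:
    """Choose k in 1..k_max by the gap statistic (global maximum rule).

    Clustering and dispersion both use 1 - Spearman distances with
    average-linkage cuts; reference datasets are drawn uniformly over the
    observed range of each feature.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    k_max = min(k_max, n)
    rng = np.random.default_rng(seed)

    def log_w_profile(data: np.ndarray) -> np.ndarray:
        D = spearman_distance(data)
        Z = linkage(squareform(D, checks=False), method="average")
        out = np.empty(k_max)
        for k in range(1, k_max + 1):
            labels = fcluster(Z, k, criterion="maxclust")
            out[k - 1] = np.log(max(_pooled_within_dispersion(D, labels), 1e-300))
        return out

    obs = log_w_profile(X)
    lo, hi = X.min(axis=0), X.max(axis=0)
    refs = np.empty((B, k_max))
    for b in range(B):
        refs[b] = log_w_profile(rng.uniform(lo, hi, size=X.shape))
    gap = refs.mean(axis=0) - obs
    se = refs.std(axis=0, ddof=1) * np.sqrt(1 + 1.0 / B)
    table = pd.DataFrame({"k": np.arange(1, k_max + 1), "log_w": obs,
                          "log_w_ref": refs.mean(axis=0), "gap": gap, "se": se})
    # Tibshirani's 1-SE rule: smallest k with gap(k) >= gap(k+1) - se(k+1).
    # On structureless data the gap curve is flat (or tilted) noise and the
    # global maximum would chase that noise; the 1-SE rule collapses to k=1.
    k_best = k_max
    for k in range(k_max - 1):
        if gap[k] >= gap[k + 1] - se[k + 1]:
            k_best = k + 1
            break
    return k_best, table


def refine_cluster(expr: np.ndarray, k_max: int = 6, B: int = 50,
                   seed: int = 0) -> np.ndarray:
    """Sub-labels within one coarse cluster (0-based ints).

    Average-linkage hierarchical clustering on 1 - Spearman distances, cut
    at the gap-statistic-optimal k.
    """
    X = np.asarray(expr, dtype=float)
    n = X.shape[0]
    if n < 3:
        return np.zeros(n, dtype=int)
    k_best, _ = gap_statistic(X, k_max=k_max, B=B, seed=seed)
    D = spearman_distance(X)
    Z = linkage(squareform(D, checks=False), method="average")
    return fcluster(Z, k_best, criterion="maxclust") - 1


def two_step_cluster(expr: np.ndarray, k: int = 20, k_max: int = 6,
                     B: int = 50, seed: int = 0,
                     cell_ids: Optional[Sequence[str]] = None
                     ) -> ClusterAssignment:
    """Louvain coarse clustering followed by per-cluster gap-statistic
    refinement; refined label = "<coarse>.<sub>"."""
    X = np.asarray(expr, dtype=float)
    n = X.shape[0]
    g = build_snn_graph(X, k=k)
    coarse = louvain_cluster(g, seed=seed)
    refined = np.empty(n, dtype=object)
    for c in np.unique(coarse):
        idx = np.flatnonzero(coarse == c)
        sub = refine_cluster(X[idx], k_max=k_max, B=B, seed=seed + int(c) + 1)
        for i, s in zip(idx, sub):
            refined[i] = f"{c}.{s}"
    ids = (np.asarray(cell_ids, object) if cell_ids is not None
           else np.array([f"cell{i}" for i in range(n)], object))
    cells = pd.DataFrame({"coarse": coarse.astype(str), "refined": refined,
                          "final": refined.copy()},
                         index=pd.Index(ids, name="cell_id"))
    return ClusterAssignment(cells=cells)


def merge_similar_clusters(labels: np.ndarray, counts, size_factors: np.ndarray,
                           min_de: int = 10, p_thresh: float = 0.01,
                           lfc: float = 1.0, floor: float = 0.1
                           ) -> tuple[np.ndarray, list]:
    """Iteratively merge the pair of clusters with the fewest DE genes while
    that count is below ``min_de``; DE counts are recomputed after every
    merge. Ties break on the lexicographically smaller pair; the merged
    cluster keeps the smaller label."""
    labels = np.asarray(labels, dtype=object).copy()
    history: list = []
    cache: Dict[tuple, int] = {}
    while True:
        uniq = sorted({l for l in labels if (labels == l).sum() >= 2})
        if len(uniq) < 2:
            break
        best = None
        for a, b in combinations(uniq, 2):
            key = (a, b)
            if key not in cache:
                cache[key] = count_de_genes(
                    counts, size_factors, labels == a, labels == b,
                    p_thresh=p_thresh, lfc=lfc, floor=floor)
            n_de = cache[key]
            if best is None or n_de < best[0]:
                best = (n_de, a, b)
        if best is None or best[0] >= min_de:
            break
        n_de, a, b = best
        labels[labels == b] = a
        history.append({"cluster_a": a, "cluster_b": b, "n_de": n_de,
                        "merged_into": a})
        cache = {k: v for k, v in cache.items() if a not in k and b not in k}
    return labels, history


def flag_contaminant_clusters(labels: np.ndarray, logexpr: np.ndarray,
                              gene_ids: Sequence[str],
                              marker_config: Optional[dict] = None,
                              margin: float = 1.0) -> pd.DataFrame:
    """Flag clusters whose median marker-panel expression exceeds the
    across-cluster median by ``margin`` log2 units, per category."""
    if marker_config is None:
        marker_config = DEFAULT_CONTAMINANT_MARKERS
    labels = np.asarray(labels)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    uniq = sorted(map(str, np.unique(labels)))
    out = pd.DataFrame({"contaminant": "", "contaminant_score": 0.0},
                       index=pd.Index(uniq, name="cluster"))
    for category, genes in marker_config.items():
        present = [gene_index[g] for g in genes if g in gene_index]
        missing = [g for g in genes if g not in gene_index]
        if missing:
            logger.warning("markers absent for %s: %s", category, missing)
        if not present:
            continue
        scores = {}
        for u in uniq:
            sub = logexpr[np.asarray(labels).astype(str) == u][:, present]
            scores[u] = float(np.median(sub.mean(axis=0)))
        baseline = np.median(list(scores.values()))
        for u in uniq:
            if scores[u] > baseline + margin:
                prev = out.loc[u, "contaminant"]
                out.loc[u, "contaminant"] = (prev + "," + category).lstrip(",")
                out.loc[u, "contaminant_score"] = max(
                    out.loc[u, "contaminant_score"], scores[u] - baseline)
    return out


def flag_doublet_clusters(labels: np.ndarray, counts,
                          sample_of_cell: np.ndarray, max_rate: float = 0.07,
                          rho_min: float = 0.9) -> pd.DataFrame:
    """Flag putative doublet clusters.

    A candidate appears at < ``max_rate`` within-sample frequency in every
    sample where it occurs. It is flagged iff its mean log2(count+1) profile
    has Spearman rho > ``rho_min`` with >= 2 clusters co-occurring in the
    same sample AND with the arithmetic mean of the best such pair's
    profiles.
    """
    labels = np.asarray(labels).astype(str)
    samples = np.asarray(sample_of_cell)
    if sp.issparse(counts):
        counts = counts.toarray()
    logc = np.log2(np.asarray(counts, float) + 1.0)
    uniq = sorted(np.unique(labels))
    profiles = {u: logc[labels == u].mean(axis=0) for u in uniq}

    freq = pd.DataFrame(0.0, index=uniq, columns=pd.unique(samples))
    for s in freq.columns:
        in_s = samples == s
        tot = in_s.sum()
        for u in uniq:
            freq.loc[u, s] = (in_s & (labels == u)).sum() / max(tot, 1)

    out = pd.DataFrame({
        "is_doublet": False, "parent1": "", "parent2": "",
        "rho_parent1": np.nan, "rho_parent2": np.nan, "rho_pair_mean": np.nan,
        "max_sample_freq": freq.max(axis=1).to_numpy(),
    }, index=pd.Index(uniq, name="cluster"))

    for u in uniq:
        present_in = [s for s in freq.columns if freq.loc[u, s] > 0]
        if not present_in or any(freq.loc[u, s] >= max_rate for s in present_in):
            continue
        cooccur = sorted({v for s in present_in for v in uniq
                          if v != u and freq.loc[v, s] > 0})
        rhos = []
        for v in cooccur:
            rho = sps.spearmanr(profiles[u], profiles[v]).statistic
            if rho > rho_min:
                rhos.append((rho, v))
        if len(rhos) < 2:
            continue
        rhos.sort(key=lambda t: (-t[0], t[1]))
        (r1, p1), (r2, p2) = rhos[0], rhos[1]
        pair_mean = 0.5 * (profiles[p1] + profiles[p2])
        rho_avg = sps.spearmanr(profiles[u], pair_mean).statistic
        out.loc[u, ["parent1", "parent2"]] = [p1, p2]
        out.loc[u, ["rho_parent1", "rho_parent2", "rho_pair_mean"]] = [r1, r2, rho_avg]
        if rho_avg > rho_min:
            out.loc[u, "is_doublet"] = True
    return out


def linkage_to_newick(Z: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Serialise a scipy linkage matrix as a Newick string with branch
    lengths equal to merge-height differences."""
    tree = to_tree(Z)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.8g}"
        inner = f"({rec(node.left, node.dist)},{rec(node.right, node.dist)})"
        return f"{inner}:{length:.8g}"

    body = f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)})" \
        if not tree.is_leaf() else leaf_names[tree.id]
    return body + ";"


def cluster_dendrogram(labels: np.ndarray, logexpr: np.ndarray
                       ) -> tuple[np.ndarray, list, str]:
    """Ward-linkage dendrogram over clusters on 1 - Spearman distances of
    per-cluster mean log expression. Returns (linkage, leaf order, newick)."""
    labels = np.asarray(labels).astype(str)
    uniq = sorted(np.unique(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters for a dendrogram")
    means = np.vstack([logexpr[labels == u].mean(axis=0) for u in uniq])
    D = spearman_distance(means)
    Z = linkage(squareform(D, checks=False), method="ward")
    return Z, uniq, linkage_to_newick(Z, uniq)
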