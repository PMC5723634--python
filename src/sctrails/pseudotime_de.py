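"""Pseudotime-dependent expression: spline fits, LRT, gradients, classes.

Per branch, each gene's log2 expression is regressed on a natural cubic
spline of pseudotime with three degrees of freedom and compared to an
intercept-only null with a Gaussian likelihood-ratio test (chi-square, 3 df).
Genes with a BH-adjusted p <= 0.01 and a fitted amplitude (max - min on a
101-point grid) of at least 0.5 log2 units are significantly
pseudotime-dependent. A trend gradient in {-1, 0, +1} is the sign of a
linear-model coefficient fitted to the spline-smoothed values, zeroed when
not significantly different from 0. Genes significant on both branches with
equal nonzero gradients are shared-direction; genes significant on at least
one branch whose gradients differ are branch-specific.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage

from .containers import NormalizedMatrix, TrajectoryAssignment, TrendTable
from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

GRID_SIZE = 101
MIN_BRANCH_CELLS = 10


def natural_spline_basis(x: np.ndarray, df: int = 3,
                         knots: Optional[np.ndarray] = None) -> np.ndarray:
    """Natural cubic spline basis (no intercept column), ``df`` columns.

    Boundary knots at the data range, ``df - 1`` interior knots at
    quantiles; the basis is linear beyond the boundary knots. Standard
    truncated-power construction.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        probs = np.linspace(0, 1, df + 1)  # df - 1 interior + 2 boundary
        knots = np.quantile(x, probs)
    knots = np.asarray(knots, dtype=float)
    if np.unique(knots).size != knots.size:
        raise ValueError("degenerate pseudotime distribution: repeated knots")
    K = len(knots)

    def d(k: int) -> np.ndarray:
        num = (np.clip(x - knots[k], 0, None) ** 3
               - np.clip(x - knots[K - 1], 0, None) ** 3)
        return num / (knots[K - 1] - knots[k])

    cols = [x]
    d_last = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - d_last)
    return np.column_stack(cols)


def fit_spline(y: np.ndarray, pseudotime: np.ndarray, df: int = 3,
               grid: Optional[np.ndarray] = None, return_design: bool = False):
    """Least-squares natural-spline fit of one or many genes on a branch.

    ``y`` is cells (or cells x genes); returns (fitted_at_cells, rss,
    grid_fitted, grid) with per-gene columns when y is a matrix.
    """
    t = np.asarray(pseudotime, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("pseudotime must be finite")
    if np.ptp(t) == 0:
        raise ValueError("all pseudotimes identical: spline fit undefined")
    Y = np.asarray(y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    probs = np.linspace(0, 1, df + 1)
    knots = np.unique(np.quantile(t, probs))
    if knots.size < 3:  # heavily tied pseudotimes: fall back to spread knots
        knots = np.linspace(t.min(), t.max(), df + 1)
    B = natural_spline_basis(t, df=df, knots=knots)
    X = np.column_stack([np.ones(len(t)), B])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ beta
    rss = ((Y - fitted) ** 2).sum(axis=0)
    if grid is None:
        grid = np.linspace(t.min(), t.max(), GRID_SIZE)
    Bg = natural_spline_basis(grid, df=df, knots=knots)
    Xg = np.column_stack([np.ones(len(grid)), Bg])
    grid_fit = Xg @ beta
    if return_design:
        return fitted, rss, grid_fit, grid, X, Xg
    if squeeze:
        return fitted[:, 0], float(rss[0]), grid_fit[:, 0], grid
    return fitted, rss, grid_fit, grid


def lrt_pseudotime(rss_alt, rss_null, n: int, df: int = 3) -> np.ndarray:
    """Gaussian likelihood-ratio p-value: 2*dlogL = n*log(RSS0/RSS1),
    compared to chi-square with ``df`` degrees of freedom."""
    rss_alt = np.atleast_1d(np.asarray(rss_alt, dtype=float))
    rss_null = np.atleast_1d(np.asarray(rss_null, dtype=float))
    if np.any(rss_null < rss_alt - 1e-8 * np.maximum(rss_null, 1.0)):
        raise ValueError("null RSS below alternative RSS: fit inconsistency")
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * np.log(np.maximum(rss_null, 1e-300)
                          / np.maximum(rss_alt, 1e-300))
    stat = np.clip(stat, 0.0, None)
    p = sps.chi2.sf(stat, df)
    p[(rss_alt <= 1e-300) & (rss_null > 1e-300)] = 0.0
    p[rss_null <= 1e-300] = 1.0
    return p


def compute_gradient(grid_values: np.ndarray, gradient_alpha: float = 0.01,
                     slope_se: Optional[np.ndarray] = None,
                     df_resid: Optional[int] = None) -> np.ndarray:
    """Trend gradient in {-1, 0, +1} from spline-smoothed grid values.

    The gradient is the sign of the simple-regression slope of the smoothed
    values against the grid, zeroed when the slope is not significantly
    different from 0. When ``slope_se`` (per-gene standard error propagated
    from the spline fit's residual noise) is supplied, the t-test uses it
    with ``df_resid`` degrees of freedom — the smoothed curve itself is
    deterministic, so this is the error scale that reflects the data.
    Without it, the test falls back to the curve's own lack-of-fit scatter
    around the line (101 grid points).
    """
    Y = np.asarray(grid_values, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    m = Y.shape[0]
    x = np.linspace(0.0, 1.0, m)
    xc = x - x.mean()
    sxx = (xc ** 2).sum()
    slope = xc @ Y / sxx
    if slope_se is not None:
        se = np.maximum(np.atleast_1d(np.asarray(slope_se, float)), 0.0)
        dof = df_resid if df_resid is not None else m - 2
    else:
        resid = Y - Y.mean(axis=0) - np.outer(xc, slope)
        rss = (resid ** 2).sum(axis=0)
        se = np.sqrt(rss / (m - 2) / sxx)
        dof = m - 2
    grad = np.zeros(Y.shape[1], dtype=int)
    scale = np.abs(Y).max(axis=0) + 1.0
    exact = se <= 1e-14
    big = np.abs(slope) > 1e-10 * scale
    grad[exact & big] = np.sign(slope[exact & big]).astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(exact, np.inf, np.abs(slope) / np.maximum(se, 1e-300))
    p = 2 * sps.t.sf(tstat, dof)
    sig = (~exact) & (p < gradient_alpha) & big
    grad[sig] = np.sign(slope[sig]).astype(int)
    # exact-fit constants: slope 0 -> gradient 0 already
    return grad[0] if squeeze else grad


def test_branch_genes(nm: NormalizedMatrix, ta: TrajectoryAssignment,
                      alpha: float = 0.01, min_amplitude: float = 0.5,
                      df: int = 3, gradient_alpha: float = 0.01) -> TrendTable:
    """Fit and test every gene on every branch; classify genes.

    BH adjustment is applied within each branch. Branches with fewer than
    10 cells are skipped with a log message.
    """
    id_index = pd.Index(nm.cell_ids)
    rows = []
    grids = {}
    per_branch_frames = []
    for branch in ("branch1", "branch2"):
        on = ta.cells.index[ta.cells["branch"] == branch]
        on = [c for c in on if c in id_index]
        if len(on) < MIN_BRANCH_CELLS:
            logger.warning("branch %s has %d cells; skipped", branch, len(on))
            continue
        loc = id_index.get_indexer(on)
        Y = nm.logexpr[loc]
        t = ta.cells.loc[on, "pseudotime"].to_numpy(float)
        # fit on the rank scale: the DPT magnitude is heavily right-skewed
        # (few extreme cells would dominate the grid), while the ordering is
        # what carries the signal
        t = (sps.rankdata(t) - 1) / (len(t) - 1)
        fitted, rss1, grid_fit, grid, X, Xg = fit_spline(Y, t, df=df,
                                                         return_design=True)
        rss0 = Y.var(axis=0) * len(on)
        p = lrt_pseudotime(rss1, rss0, n=len(on), df=df)
        padj = bh_adjust(p)
        amplitude = grid_fit.max(axis=0) - grid_fit.min(axis=0)
        # propagate spline-fit noise into the trend slope's standard error
        m = Xg.shape[0]
        xg = np.linspace(0.0, 1.0, m)
        a = (xg - xg.mean()) / ((xg - xg.mean()) ** 2).sum()
        w = np.linalg.pinv(X).T @ (Xg.T @ a)
        df_resid = len(on) - X.shape[1]
        sigma = np.sqrt(rss1 / max(df_resid, 1))
        slope_se = sigma * np.linalg.norm(w)
        grad = compute_gradient(grid_fit, gradient_alpha=gradient_alpha,
                                slope_se=slope_se, df_resid=df_resid)
        sig = (padj <= alpha) & (amplitude >= min_amplitude)
        frame = pd.DataFrame({
            "gene_id": nm.gene_ids, "branch": branch, "lrt_stat_p": p,
            "p_adj": padj, "amplitude": amplitude, "gradient": grad,
            "significant": sig})
        per_branch_frames.append(frame)
        grids[branch] = pd.DataFrame(grid_fit.T, index=pd.Index(nm.gene_ids,
                                                                name="gene_id"))
    if not per_branch_frames:
        raise ValueError("no branch had enough cells for spline testing")
    per_branch = pd.concat(per_branch_frames, ignore_index=True)

    per_gene = classify_genes(per_branch)
    params = {"alpha": alpha, "min_amplitude": min_amplitude, "df": df,
              "gradient_alpha": gradient_alpha, "grid_size": GRID_SIZE}
    return TrendTable(per_branch=per_branch, per_gene=per_gene, grids=grids,
                      params=params)


def classify_genes(per_branch: pd.DataFrame) -> pd.DataFrame:
    """Shared-direction vs branch-specific vs none, from per-branch results.

    shared_same_direction: significant on both branches, equal nonzero
    gradients. branch_specific: significant on >= 1 branch, gradients
    differ (including sign vs 0). Everything else: none.
    """
    wide_sig = per_branch.pivot(index="gene_id", columns="branch",
                                values="significant")
    wide_grad = per_branch.pivot(index="gene_id", columns="branch",
                                 values="gradient")
    branches = list(wide_sig.columns)
    out = pd.DataFrame({"classification": "none"}, index=wide_sig.index)
    if len(branches) == 2:
        b1, b2 = branches
        s1 = wide_sig[b1].fillna(False).astype(bool)
        s2 = wide_sig[b2].fillna(False).astype(bool)
        g1 = wide_grad[b1].fillna(0).astype(int)
        g2 = wide_grad[b2].fillna(0).astype(int)
        shared = s1 & s2 & (g1 == g2) & (g1 != 0)
        specific = (s1 | s2) & (g1 != g2)
        out.loc[specific, "classification"] = "branch_specific"
        out.loc[shared, "classification"] = "shared_same_direction"
        out["gradient_branch1"] = g1
        out["gradient_branch2"] = g2
        out["significant_any"] = s1 | s2
    return out


def cluster_trends(tt: TrendTable, branch: str, min_cluster_size: int = 5
                   ) -> pd.DataFrame:
    """Cluster z-scaled spline trends of the branch's significant genes.

    Average-linkage hierarchical clustering of the z-scaled 101-point
    fitted curves; the tree is cut at the largest merge-height gap
    (a simplified variable-height cut) and clusters smaller than
    ``min_cluster_size`` are absorbed into the nearest cluster by mean
    profile. Genes are ordered by cluster, then by the grid position of
    their fitted maximum (heatmap order).
    """
    sig_genes = per_branch_significant(tt, branch)
    if len(sig_genes) < 10:
        raise ValueError("need >= 10 significant genes to cluster trends")
    G = tt.grids[branch].loc[sig_genes].to_numpy(float)
    sd = G.std(axis=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("%d zero-variance trends dropped", int((~keep).sum()))
    G, sig_genes = G[keep], [g for g, k in zip(sig_genes, keep) if k]
    Z01 = (G - G.mean(axis=1, keepdims=True)) / G.std(axis=1, keepdims=True)

    Zl = linkage(Z01, method="average", metric="euclidean")
    heights = Zl[:, 2]
    if len(heights) > 1:
        gaps = np.diff(heights)
        i = int(np.argmax(gaps))
        cut = 0.5 * (heights[i] + heights[i + 1])
    else:
        cut = heights[0] + 1.0
    labels = fcluster(Zl, cut, criterion="distance")

    # absorb undersized clusters into the nearest big one
    sizes = pd.Series(labels).value_counts()
    big = sizes.index[sizes >= min_cluster_size]
    if len(big) == 0:
        labels = np.ones_like(labels)
    else:
        centroids = {b: Z01[labels == b].mean(axis=0) for b in big}
        for lab in sizes.index[sizes < min_cluster_size]:
            for i in np.flatnonzero(labels == lab):
                dists = {b: np.linalg.norm(Z01[i] - c)
                         for b, c in centroids.items()}
                labels[i] = min(dists, key=lambda b: (dists[b], b))
    relabel = {old: new for new, old in
               enumerate(pd.unique(labels), start=1)}
    labels = np.array([relabel[l] for l in labels])

    argmax_pos = G.argmax(axis=1)
    out = pd.DataFrame({"trend_cluster": labels, "peak_position": argmax_pos},
                       index=pd.Index(sig_genes, name="gene_id"))
    out = out.sort_values(["trend_cluster", "peak_position"], kind="stable")
    out["heatmap_order"] = np.arange(len(out))
    return out


def per_branch_significant(tt: TrendTable, branch: str) -> list:
    sub = tt.per_branch
    mask = (sub["branch"] == branch) & sub["significant"]
    return sub.loc[mask, "gene_id"].tolist()
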