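"""Negative-binomial differential expression with a fold-change threshold.

The two-group test asks not merely whether a gene differs, but whether its
|log2 fold change| significantly exceeds a threshold (default 1): the null
hypothesis is |lfc| <= threshold, tested with a shifted Wald statistic under
an NB variance model with moderated (trend-shrunk) dispersions. Genes with
an observed |lfc| inside the threshold get p = 1 by construction. Lowly
expressed genes (mean normalised count below 0.1) are excluded before
testing, and Benjamini-Hochberg adjustment is applied across tested genes.

Marker finding runs all pairwise contrasts for each cluster and aggregates
by worst-case rank, so a top marker must beat every other cluster.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

PRIOR_DF = 10.0  # strength of dispersion shrinkage toward the trend


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)):
        raise ValueError("bh_adjust: NaN p-values")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _normalized(counts, size_factors: np.ndarray) -> np.ndarray:
    if sp.issparse(counts):
        counts = counts.toarray()
    return np.asarray(counts, dtype=float) / np.asarray(size_factors, float)[:, None]


def filter_expressed(counts, size_factors: np.ndarray,
                     floor: float = 0.1) -> np.ndarray:
    """Boolean gene mask: overall mean normalised count >= floor.

    Genes strictly below the floor are dropped; a gene at exactly the floor
    is kept.
    """
    mean = _normalized(counts, size_factors).mean(axis=0)
    keep = mean >= floor
    if not keep.any():
        raise ValueError("no testable genes: all means below the expression floor")
    return keep


def estimate_dispersion(y_a: np.ndarray, y_b: np.ndarray) -> np.ndarray:
    """Per-gene NB dispersion from normalised counts of two groups.

    Method-of-moments within each group, pooled by residual df, then shrunk
    toward a lowess mean-dispersion trend with prior df 10. Non-positive
    and undefined estimates are clipped to 0.
    """
    phis, weights = [], []
    for y in (y_a, y_b):
        n = y.shape[0]
        mu = y.mean(axis=0)
        v = y.var(axis=0, ddof=1) if n > 1 else np.zeros(y.shape[1])
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.where(mu > 0, (v - mu) / np.maximum(mu, 1e-300) ** 2, 0.0)
        phis.append(np.clip(phi, 0.0, None))
        weights.append(max(n - 1, 0))
    w = np.asarray(weights, float)
    if w.sum() == 0:
        raise ValueError("need >= 2 cells in at least one group")
    phi_raw = (phis[0] * w[0] + phis[1] * w[1]) / w.sum()

    mu_all = np.vstack([y_a, y_b]).mean(axis=0)
    log_mu = np.log10(mu_all + 1e-8)
    if phi_raw.size >= 20:
        fit = lowess(phi_raw, log_mu, frac=0.5, it=2, return_sorted=True)
        ux, inv = np.unique(fit[:, 0], return_inverse=True)
        uy = np.bincount(inv, weights=fit[:, 1]) / np.bincount(inv)
        trend = np.clip(np.interp(log_mu, ux, uy), 0.0, None)
    else:
        trend = np.full_like(phi_raw, phi_raw.mean())
    resid_df = float(w.sum())
    phi = (resid_df * phi_raw + PRIOR_DF * trend) / (resid_df + PRIOR_DF)
    return np.clip(phi, 0.0, None)


def de_test_treat(counts, size_factors: np.ndarray, group_mask_a: np.ndarray,
                  group_mask_b: np.ndarray, lfc_threshold: float = 1.0,
                  alpha: float = 0.01, floor: float = 0.1,
                  gene_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Fold-change-threshold test between two groups of cells.

    Returns one row per tested gene: mean_a, mean_b, log2fc, dispersion,
    p_value, p_adj, passed. ``lfc_threshold=0`` reduces to an ordinary
    two-sided Wald test.
    """
    group_mask_a = np.asarray(group_mask_a, bool)
    group_mask_b = np.asarray(group_mask_b, bool)
    if group_mask_a.sum() < 2 or group_mask_b.sum() < 2:
        raise ValueError("each group needs at least 2 cells")
    y = _normalized(counts, size_factors)
    keep = filter_expressed(counts, size_factors, floor=floor)
    y = y[:, keep]
    y_a, y_b = y[group_mask_a], y[group_mask_b]
    n_a, n_b = y_a.shape[0], y_b.shape[0]

    phi = estimate_dispersion(y_a, y_b)
    m_a, m_b = y_a.mean(axis=0), y_b.mean(axis=0)
    m_a_s = m_a + 0.5 / n_a  # pseudo-counts bound the fold change
    m_b_s = m_b + 0.5 / n_b
    lfc = np.log2(m_a_s) - np.log2(m_b_s)

    var_a = (m_a_s + phi * m_a_s ** 2) / n_a
    var_b = (m_b_s + phi * m_b_s ** 2) / n_b
    se = np.sqrt(var_a / m_a_s ** 2 + var_b / m_b_s ** 2) / np.log(2.0)
    se = np.maximum(se, 1e-12)

    tau = float(lfc_threshold)
    abs_lfc = np.abs(lfc)
    if tau > 0:
        p = np.where(
            abs_lfc <= tau, 1.0,
            np.minimum(1.0, sps.norm.sf((abs_lfc - tau) / se)
                       + sps.norm.sf((abs_lfc + tau) / se)))
    else:
        p = np.minimum(1.0, 2.0 * sps.norm.sf(abs_lfc / se))
    padj = bh_adjust(p)

    ids = (np.asarray(gene_ids, object)[keep] if gene_ids is not None
           else np.array([f"g{i}" for i in np.flatnonzero(keep)], object))
    out = pd.DataFrame({
        "mean_a": m_a, "mean_b": m_b, "log2fc": lfc, "dispersion": phi,
        "p_value": p, "p_adj": padj, "passed": padj <= alpha,
    }, index=pd.Index(ids, name="gene_id"))
    out.attrs["params"] = {"lfc_threshold": tau, "alpha": alpha, "floor": floor,
                           "n_a": n_a, "n_b": n_b}
    return out


def count_de_genes(counts, size_factors, mask_a, mask_b,
                   p_thresh: float = 0.01, lfc: float = 1.0,
                   floor: float = 0.1) -> int:
    """Number of genes with raw p < p_thresh in the |lfc|-threshold test.

    This is the merge criterion used by the clustering step (unadjusted p,
    threshold test already enforcing |log2fc| > lfc).
    """
    res = de_test_treat(counts, size_factors, mask_a, mask_b,
                        lfc_threshold=lfc, floor=floor)
    return int((res["p_value"] < p_thresh).sum())


def find_markers(labels: np.ndarray, logexpr: np.ndarray, counts,
                 size_factors: np.ndarray, gene_ids: Sequence[str],
                 min_median: float = 1.0) -> dict:
    """Per-cluster ranked marker tables via pairwise worst-case ranking.

    Genes are pre-filtered to those with median log expression >= min_median
    in at least one cluster. Within each pairwise contrast genes are ranked
    by (upregulated first, then p-value); a gene's score for a cluster is
    its worst rank over all contrasts, so top markers separate the cluster
    from every other one.
    """
    labels = np.asarray(labels)
    gene_ids = np.asarray(gene_ids, object)
    uniq = [u for u in pd.unique(labels)]
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters for marker finding")

    medians = np.vstack([np.median(logexpr[labels == u], axis=0) for u in uniq])
    keep = (medians >= min_median).any(axis=0)
    if not keep.any():
        return {u: pd.DataFrame() for u in uniq}
    kept_ids = gene_ids[keep]
    counts_k = counts[:, np.flatnonzero(keep)]

    tables = {}
    for u in uniq:
        mask_u = labels == u
        if mask_u.sum() < 2:
            logger.warning("cluster %s has <2 cells; skipped in marker finding", u)
            continue
        worst = np.zeros(keep.sum())
        pmin = np.ones(keep.sum())
        lfc_min = np.full(keep.sum(), np.inf)
        for v in uniq:
            if v == u or (labels == v).sum() < 2:
                continue
            res = de_test_treat(counts_k, size_factors, mask_u, labels == v,
                                lfc_threshold=0.0, floor=0.0,
                                gene_ids=kept_ids)
            res = res.loc[kept_ids]
            order_key = list(zip(res["log2fc"] <= 0, res["p_value"]))
            ranks = pd.Series(order_key).rank(method="min").to_numpy()
            worst = np.maximum(worst, ranks)
            pmin = np.minimum(pmin, res["p_value"].to_numpy())
            lfc_min = np.minimum(lfc_min, res["log2fc"].to_numpy())
        tab = pd.DataFrame({
            "rank_score": worst, "min_log2fc": lfc_min, "best_p": pmin,
        }, index=pd.Index(kept_ids, name="gene_id"))
        tab = tab.sort_values(["rank_score", "best_p"], kind="stable")
        tab["rank"] = np.arange(1, len(tab) + 1)
        tables[u] = tab
    return tables
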