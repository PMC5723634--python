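"""Per-sample adaptive quality control, normalisation and HVG selection.

QC thresholds on genes detected and total UMIs are set per sample at three
median absolute deviations below the sample median, with hard floors
(defaults: 500 genes, 1000 UMIs). Cells at or above 5% mitochondrial UMIs
are removed as non-viable, and cells whose barcode appears in more than one
sample are excluded as potential index-swapping artifacts.

Normalisation uses a pooling-deconvolution size-factor estimator: cells are
arranged on a ring ordered by library size, overlapping pools of several
sizes are summed, each pool sum is compared with an average reference
profile, and the resulting linear system is solved for per-cell factors in
least squares. Highly variable genes are those whose log-expression variance
exceeds a fitted mean-variance trend by at least ``min_bio`` with a
significant (BH-adjusted) one-sided test.
"""

from __future__ import annotations

import logging
import re
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps
from scipy.sparse.linalg import lsqr
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import CountMatrix, NormalizedMatrix, QCReport
from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

DEFAULT_POOL_SIZES = (21, 26, 31, 36, 41)
MIN_CELLS_FOR_MAD = 10


def compute_cell_qc(cm: CountMatrix, mito_pattern: str = "^mt-") -> QCReport:
    """Per-cell totals, genes detected and mitochondrial fraction."""
    total = cm.library_sizes().astype(float)
    detected = np.asarray((cm.counts > 0).sum(axis=1)).ravel()
    mito_mask = np.array([bool(re.match(mito_pattern, g)) for g in cm.gene_ids])
    if not mito_mask.any():
        logger.warning("mito pattern %r matched no genes; mito_fraction set to 0",
                       mito_pattern)
        mito = np.zeros(cm.n_cells)
    else:
        mito = np.asarray(cm.counts[:, mito_mask].sum(axis=1)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1e-300), 0.0)
    cells = pd.DataFrame({
        "total_umis": total.astype(int), "genes_detected": detected,
        "mito_fraction": mito_frac, "sample": cm.sample_of_cell,
    }, index=pd.Index(cm.cell_ids, name="cell_id"))
    return QCReport(cells=cells, params={"mito_pattern": mito_pattern})


def mad_threshold(values: Sequence[float], n_mads: float = 3.0,
                  floor: float = 0.0) -> float:
    """max(median - n_mads * 1.4826 * MAD, floor).

    The 1.4826 factor makes the MAD consistent with the standard deviation
    under normality.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("mad_threshold: empty input")
    med = np.median(values)
    mad = 1.4826 * np.median(np.abs(values - med))
    return float(max(med - n_mads * mad, floor))


def flag_shared_barcodes(cm: CountMatrix) -> np.ndarray:
    """True for every cell whose raw barcode occurs in >= 2 distinct samples."""
    df = pd.DataFrame({"bc": cm.raw_barcodes, "sample": cm.sample_of_cell})
    n_samples = df.groupby("bc")["sample"].nunique()
    shared = set(n_samples.index[n_samples >= 2])
    return np.array([bc in shared for bc in cm.raw_barcodes])


def apply_qc(cm: CountMatrix, n_mads: float = 3.0, gene_floor: float = 500,
             umi_floor: float = 1000, mito_cut: float = 0.05,
             mito_pattern: str = "^mt-",
             fixed_thresholds: Optional[pd.DataFrame] = None
             ) -> tuple[CountMatrix, QCReport]:
    """Adaptive per-sample QC; returns the passing cells and a full report.

    A cell fails if genes detected or total UMIs fall below the sample's
    adaptive threshold, if its mitochondrial fraction is at or above
    ``mito_cut`` (the cut is inclusive), or if its barcode is shared across
    samples. Shared-barcode cells are excluded before threshold estimation
    so swapped cells cannot bias the medians. ``fixed_thresholds`` (indexed
    by sample, columns gene_threshold/umi_threshold) bypasses estimation.
    """
    report = compute_cell_qc(cm, mito_pattern=mito_pattern)
    cells = report.cells
    shared = flag_shared_barcodes(cm)

    thresholds = {}
    for sample in cm.samples:
        in_sample = (cells["sample"] == sample).to_numpy() & ~shared
        if fixed_thresholds is not None:
            g_thr = float(fixed_thresholds.loc[sample, "gene_threshold"])
            u_thr = float(fixed_thresholds.loc[sample, "umi_threshold"])
        elif in_sample.sum() < MIN_CELLS_FOR_MAD:
            logger.warning("sample %s has %d cells; using floors instead of MADs",
                           sample, int(in_sample.sum()))
            g_thr, u_thr = float(gene_floor), float(umi_floor)
        else:
            g_thr = mad_threshold(cells.loc[in_sample, "genes_detected"],
                                  n_mads, gene_floor)
            u_thr = mad_threshold(cells.loc[in_sample, "total_umis"],
                                  n_mads, umi_floor)
        thresholds[sample] = (g_thr, u_thr)

    g_thr_of = cells["sample"].map({s: t[0] for s, t in thresholds.items()}).to_numpy()
    u_thr_of = cells["sample"].map({s: t[1] for s, t in thresholds.items()}).to_numpy()
    flags = {
        "low_genes": cells["genes_detected"].to_numpy() < g_thr_of,
        "low_umi": cells["total_umis"].to_numpy() < u_thr_of,
        "high_mito": cells["mito_fraction"].to_numpy() >= mito_cut,
        "shared_barcode": shared,
    }
    reasons = [",".join(name for name in flags if flags[name][i])
               for i in range(len(cells))]
    cells = cells.assign(reasons=reasons)
    cells["pass"] = cells["reasons"] == ""

    thr_df = pd.DataFrame(
        {"gene_threshold": {s: t[0] for s, t in thresholds.items()},
         "umi_threshold": {s: t[1] for s, t in thresholds.items()}})
    thr_df.index.name = "sample"
    out_report = QCReport(cells=cells, sample_thresholds=thr_df, params={
        "n_mads": n_mads, "gene_floor": gene_floor, "umi_floor": umi_floor,
        "mito_cut": mito_cut, "mito_pattern": mito_pattern})
    passing = cm.subset_cells(cells["pass"].to_numpy())
    return passing, out_report


def _ring_order(lib_sizes: np.ndarray) -> np.ndarray:
    """Arrange cells on a ring so library size rises then falls smoothly."""
    order = np.argsort(lib_sizes, kind="stable")
    return np.concatenate([order[0::2], order[1::2][::-1]])


def compute_size_factors(cm: CountMatrix,
                         pool_sizes: Optional[Sequence[int]] = None
                         ) -> np.ndarray:
    """Pooling-deconvolution size factors, rescaled to mean 1.

    Pool sums are robust to zero inflation in single cells; each pool's
    summed profile is compared to the average profile by a median ratio,
    giving one linear equation in the member cells' factors. Low-weight
    library-size anchor equations make the system full rank.
    """
    counts = sp.csr_matrix(cm.counts, dtype=float)
    n = counts.shape[0]
    lib = np.asarray(counts.sum(axis=1)).ravel()
    if np.any(lib <= 0):
        raise ValueError("compute_size_factors: all-zero cells present")
    if pool_sizes is None:
        pool_sizes = [s for s in DEFAULT_POOL_SIZES if s <= max(n // 2, 2)]
        if not pool_sizes:
            pool_sizes = [max(2, n // 2)]
    if max(pool_sizes) > n:
        raise ValueError("largest pool size exceeds the number of cells")

    # reference = average of depth-scaled profiles
    scaled = counts.multiply((lib.mean() / lib)[:, None]).tocsr()
    ref = np.asarray(scaled.mean(axis=0)).ravel()
    use = ref > 0
    ref_use = ref[use]
    scaled_use = np.asarray(scaled[:, use].todense())

    ring = _ring_order(lib)
    ring_mat = scaled_use[ring]
    csum = np.vstack([np.zeros(ring_mat.shape[1]),
                      np.cumsum(np.vstack([ring_mat, ring_mat]), axis=0)])
    rows, cols, vals, rhs = [], [], [], []
    eq = 0
    for size in pool_sizes:
        starts = np.arange(n)
        pool_sums = csum[starts + size] - csum[starts]  # n x genes, ring-wrapped
        ratios = np.median(pool_sums / ref_use, axis=1)
        member_cols = ring[(starts[:, None] + np.arange(size)) % n]
        rows.extend(np.repeat(np.arange(eq, eq + n), size).tolist())
        cols.extend(member_cols.ravel().tolist())
        vals.extend([1.0] * (n * size))
        rhs.extend(ratios.tolist())
        eq += n
    # low-weight anchors: cells are pre-scaled by library size, so the
    # composition-relative factor theta is anchored at 1
    w = np.sqrt(0.1)
    for c in range(n):
        rows.append(eq)
        cols.append(c)
        vals.append(w)
        rhs.append(w)
        eq += 1
    A = sp.csr_matrix((vals, (rows, cols)), shape=(eq, n))
    theta = lsqr(A, np.asarray(rhs), atol=1e-10, btol=1e-10, iter_lim=10000)[0]
    if np.any(theta <= 0):
        pos = theta[theta > 0]
        if pos.size == 0:
            raise ValueError("deconvolution produced no positive factors")
        logger.warning("clipping %d non-positive size factors", int((theta <= 0).sum()))
        theta = np.where(theta <= 0, pos.min(), theta)
    # undo the library pre-scaling: factor = composition ratio x depth
    sf = theta * lib
    return sf / sf.mean()


def log_normalize(cm: CountMatrix, size_factors: np.ndarray) -> NormalizedMatrix:
    """logexpr[c, g] = log2(count[c, g] / size_factor[c] + 1)."""
    size_factors = np.asarray(size_factors, dtype=float)
    if size_factors.shape[0] != cm.n_cells:
        raise ValueError("size factors not aligned to cells")
    dense = cm.counts.toarray() / size_factors[:, None]
    return NormalizedMatrix(
        logexpr=np.log2(dense + 1.0), size_factors=size_factors,
        cell_ids=cm.cell_ids, gene_ids=cm.gene_ids,
        sample_of_cell=cm.sample_of_cell, timepoint_of_cell=cm.timepoint_of_cell)


def fit_mean_variance_trend(nm: NormalizedMatrix, frac: float = 0.3) -> pd.DataFrame:
    """Per-gene mean/variance of log expression and a smooth technical trend.

    The trend is a lowess fit of variance against mean across all genes,
    evaluated at each gene's mean and clipped to be non-negative. It assumes
    most genes' variance is technical, so the bulk of the scatter defines
    the trend.
    """
    if nm.n_cells < 2:
        raise ValueError("need at least 2 cells to estimate variances")
    if nm.n_genes < 50:
        raise ValueError("too few genes (<50) for a reliable trend")
    mean = nm.logexpr.mean(axis=0)
    var = nm.logexpr.var(axis=0, ddof=1)
    fit = lowess(var, mean, frac=frac, it=3, return_sorted=True)
    xs, ys = fit[:, 0], fit[:, 1]
    # average duplicates so evaluation is independent of gene order
    ux, inv = np.unique(xs, return_inverse=True)
    uy = np.bincount(inv, weights=ys) / np.bincount(inv)
    trend = np.interp(mean, ux, uy)
    trend = np.clip(trend, 1e-8, None)
    return pd.DataFrame({"mean": mean, "var": var, "trend": trend},
                        index=pd.Index(nm.gene_ids, name="gene_id"))


def select_hvgs(stats: pd.DataFrame, n_cells: int, min_bio: float = 0.5,
                alpha: float = 0.05) -> pd.DataFrame:
    """Flag genes whose variance exceeds the trend by >= min_bio, testing
    observed/trend against a scaled chi-square with n_cells - 1 df (one-sided),
    BH-adjusted at ``alpha``."""
    df = int(n_cells) - 1
    out = stats.copy()
    out["bio"] = out["var"] - out["trend"]
    out["p_value"] = sps.chi2.sf(df * out["var"] / out["trend"], df)
    out["p_adj"] = bh_adjust(out["p_value"].to_numpy())
    out["is_hvg"] = (out["bio"] >= min_bio) & (out["p_adj"] <= alpha)
    out.attrs["params"] = {"min_bio": min_bio, "alpha": alpha}
    return out


def preprocess_matrix(cm: CountMatrix, qc_params: Optional[dict] = None,
                      hvg_params: Optional[dict] = None
                      ) -> tuple[CountMatrix, QCReport, NormalizedMatrix, pd.DataFrame]:
    """Convenience chain: QC -> size factors -> log normalise -> HVGs."""
    qc_params = qc_params or {}
    hvg_params = hvg_params or {}
    passed, report = apply_qc(cm, **qc_params)
    sf = compute_size_factors(passed)
    nm = log_normalize(passed, sf)
    stats = fit_mean_variance_trend(nm)
    hvgs = select_hvgs(stats, n_cells=nm.n_cells, **hvg_params)
    return passed, report, nm, hvgs
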