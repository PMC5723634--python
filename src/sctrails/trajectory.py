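"""Diffusion-map embedding, diffusion pseudotime and branch assignment.

The embedding uses a Gaussian kernel on Euclidean distances of log HVG
expression, sparsified to union-symmetrised k-nearest neighbours, with anisotropic
density normalisation (alpha = 1) and a row-normalised transition operator.
The trivial stationary eigenvector is dropped; diffusion components are the
remaining right eigenvectors ordered by decreasing eigenvalue, each oriented
so its largest-magnitude entry is positive (a fixed sign convention making
reruns bit-identical).

Trajectory anchors follow an extremal-cell rule: the root is the cell with
the largest value on the second diffusion component, the two branch tips
are the cells with the largest and smallest values on the first. Diffusion
pseudotime (DPT) between two cells is the Euclidean distance between their
rows of the accumulated operator, computed in closed form from eigenvectors
scaled by lambda/(1-lambda); pseudotime is DPT from the root. Cells join the
branch whose tip minimises the triangle excess
dpt(c, tip) + dpt(root, c) - dpt(root, tip).
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .containers import DiffusionEmbedding, TrajectoryAssignment

logger = logging.getLogger(__name__)


def _knn_kernel(X: np.ndarray, knn: int) -> tuple[sp.csr_matrix, float]:
    """Gaussian kernel on symmetrised kNN edges plus unit diagonal.

    The kNN adjacency is symmetrised by union (an edge survives if either
    endpoint lists the other among its k nearest neighbours): on noisy
    high-dimensional expression data the stricter mutual-kNN rule shatters
    the graph into many singletons. Global sigma is the median distance to
    the ceil(knn/2)-th neighbour.
    """
    from sklearn.neighbors import NearestNeighbors

    n = X.shape[0]
    nn = NearestNeighbors(n_neighbors=min(knn + 1, n)).fit(X)
    dist, idx = nn.kneighbors(X)
    # drop self column (first neighbour at distance 0)
    dist, idx = dist[:, 1:], idx[:, 1:]
    mid = int(np.ceil(knn / 2)) - 1
    sigma = float(np.median(dist[:, min(mid, dist.shape[1] - 1)]))
    if sigma <= 0:
        sigma = max(float(np.median(dist[dist > 0])) if (dist > 0).any() else 1.0,
                    1e-12)

    rows = np.repeat(np.arange(n), idx.shape[1])
    A = sp.csr_matrix((np.exp(-dist.ravel() ** 2 / (2 * sigma ** 2)),
                       (rows, idx.ravel())), shape=(n, n))
    K = A.maximum(A.T) + sp.identity(n, format="csr")
    return K.tocsr(), sigma, dist[:, -1].copy()


def largest_connected_component(expr: np.ndarray, knn: int = 30) -> np.ndarray:
    """Indices of cells in the largest connected component of the kNN
    kernel graph. Used to restrict trajectory inference to one connected
    manifold when the input mixes disconnected populations."""
    X = np.asarray(expr, dtype=float)
    K, _, _ = _knn_kernel(X, min(knn, X.shape[0] - 1))
    n_comp, labels = connected_components(K, directed=False)
    if n_comp == 1:
        return np.arange(X.shape[0])
    sizes = np.bincount(labels)
    keep = np.flatnonzero(labels == np.argmax(sizes))
    logger.warning("kernel graph has %d components; restricting to the "
                   "largest (%d of %d cells)", n_comp, len(keep), X.shape[0])
    return keep


def compute_diffusion_map(expr: np.ndarray, n_components: int = 10,
                          knn: int = 30,
                          cell_ids: Optional[Sequence[str]] = None
                          ) -> DiffusionEmbedding:
    """Eigendecompose the density-normalised diffusion operator.

    Solved densely through the symmetric conjugate operator
    D^{-1/2} K~ D^{-1/2}, which shares eigenvalues with the transition
    matrix; right eigenvectors are recovered as D^{-1/2} u.
    """
    X = np.asarray(expr, dtype=float)
    n = X.shape[0]
    if n < n_components + 2:
        raise ValueError("need at least n_components + 2 cells")
    K, sigma, kth_dist = _knn_kernel(X, knn)

    n_comp, comp_labels = connected_components(K, directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp_labels)
        raise ValueError(
            f"kernel graph is disconnected (component sizes {sorted(sizes)}); "
            "increase knn or the kernel bandwidth")

    q = np.asarray(K.sum(axis=1)).ravel()  # density estimate
    Kt = sp.diags(1.0 / q) @ K @ sp.diags(1.0 / q)  # anisotropic alpha = 1
    d = np.asarray(Kt.sum(axis=1)).ravel()
    d_isqrt = 1.0 / np.sqrt(d)
    S = sp.diags(d_isqrt) @ Kt @ sp.diags(d_isqrt)
    S = np.asarray(S.todense())
    S = 0.5 * (S + S.T)

    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    psi = d_isqrt[:, None] * evecs  # right eigenvectors of the operator

    # drop the trivial lambda = 1 component
    evals, psi = evals[1:n_components + 1], psi[:, 1:n_components + 1]
    evals = np.clip(evals, None, 1.0 - 1e-12)
    # fixed sign convention: largest-magnitude entry positive
    for j in range(psi.shape[1]):
        i = np.argmax(np.abs(psi[:, j]))
        if psi[i, j] < 0:
            psi[:, j] = -psi[:, j]

    ids = (np.asarray(cell_ids, object) if cell_ids is not None
           else np.array([f"cell{i}" for i in range(n)], object))
    return DiffusionEmbedding(
        eigenvalues=evals, components=psi, cell_ids=ids, ref_data=X,
        sigma=sigma, knn=knn, density_q=q, row_degree=d,
        ref_kth_dist=kth_dist)


def select_tips(emb: DiffusionEmbedding) -> tuple[str, str, str]:
    """(root, tip1, tip2): root maximises DC2, tips are the extremes of DC1.

    Ties resolve to the smaller cell index (argmax convention) and are
    logged; coincident root and tip indicate degenerate geometry.
    """
    if emb.n_components < 2:
        raise ValueError("need at least 2 diffusion components")
    dc1, dc2 = emb.components[:, 0], emb.components[:, 1]
    for name, v in (("DC1", dc1), ("DC2", dc2)):
        if (v == v.max()).sum() > 1 or (v == v.min()).sum() > 1:
            logger.warning("tie on %s extremum; resolved by cell index", name)
    tip1_i, tip2_i = int(np.argmax(dc1)), int(np.argmin(dc1))
    # Eigenvector signs are arbitrary; orient DC2 so its maximum is distinct
    # from both tips (DC2 is often a secondary mode of the same path, with
    # one extreme coinciding with a DC1 tip — the other extreme anchors the
    # trajectory origin).
    root_i = int(np.argmax(dc2))
    if root_i in (tip1_i, tip2_i):
        alt = int(np.argmin(dc2))
        logger.info("DC2 maximum coincides with a tip; using the opposite "
                    "extreme as root")
        root_i = alt
    if len({root_i, tip1_i, tip2_i}) < 3:
        raise ValueError("degenerate geometry: root coincides with a tip")
    ids = emb.cell_ids
    return str(ids[root_i]), str(ids[tip1_i]), str(ids[tip2_i])


def dpt_coordinates(emb: DiffusionEmbedding) -> np.ndarray:
    """Cells x components matrix whose pairwise Euclidean distances are the
    diffusion-pseudotime metric (eigenvectors scaled by lambda/(1-lambda))."""
    lam = emb.eigenvalues
    if np.any(lam >= 1.0):
        raise ValueError("eigenvalue 1 among retained components (disconnected graph)")
    return emb.components * (lam / (1.0 - lam))[None, :]


def compute_dpt(emb: DiffusionEmbedding, root: str) -> pd.Series:
    """Diffusion pseudotime of every cell relative to the root cell."""
    coords = dpt_coordinates(emb)
    ids = list(emb.cell_ids)
    r = ids.index(root)
    pt = np.linalg.norm(coords - coords[r], axis=1)
    return pd.Series(pt, index=pd.Index(emb.cell_ids, name="cell_id"),
                     name="pseudotime")


def assign_branches(emb: DiffusionEmbedding, root: str, tip1: str, tip2: str
                    ) -> TrajectoryAssignment:
    """Assign every cell to the branch whose tip minimises the triangle
    excess e_b(c) = dpt(c, tip_b) + dpt(root, c) - dpt(root, tip_b).
    Ties go to branch1 (logged)."""
    coords = dpt_coordinates(emb)
    ids = list(emb.cell_ids)
    r, t1, t2 = ids.index(root), ids.index(tip1), ids.index(tip2)
    d_root = np.linalg.norm(coords - coords[r], axis=1)
    e1 = np.linalg.norm(coords - coords[t1], axis=1) + d_root - d_root[t1]
    e2 = np.linalg.norm(coords - coords[t2], axis=1) + d_root - d_root[t2]
    ties = np.isclose(e1, e2)
    if ties.any():
        logger.info("%d branch-assignment ties resolved to branch1", int(ties.sum()))
    branch = np.where(e1 <= e2, "branch1", "branch2")
    cells = pd.DataFrame({
        "pseudotime": d_root, "branch": branch, "e_branch1": e1, "e_branch2": e2,
    }, index=pd.Index(emb.cell_ids, name="cell_id"))
    return TrajectoryAssignment(root=root, tip1=tip1, tip2=tip2, cells=cells)


def infer_trajectory(expr: np.ndarray, n_components: int = 10, knn: int = 30,
                     cell_ids: Optional[Sequence[str]] = None
                     ) -> tuple[DiffusionEmbedding, TrajectoryAssignment]:
    """Embedding + tip selection + pseudotime + branches in one call."""
    emb = compute_diffusion_map(expr, n_components=n_components, knn=knn,
                                cell_ids=cell_ids)
    root, tip1, tip2 = select_tips(emb)
    return emb, assign_branches(emb, root, tip1, tip2)


def project_cells(emb: DiffusionEmbedding, new_expr: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Nystroem extension of held-out cells onto the reference embedding.

    Kernel rows from new cells to the reference cells use the stored sigma
    and kNN sparsity plus the same density normalisation; coordinates are
    kernel-weighted combinations of reference eigenvectors scaled by
    1/lambda. Returns (coordinates, placed_mask); cells with zero kernel
    mass to every reference are flagged unplaced.
    """
    from sklearn.neighbors import NearestNeighbors

    Xr = emb.ref_data
    Xn = np.asarray(new_expr, dtype=float)
    if Xn.shape[1] != Xr.shape[1]:
        raise ValueError("new cells must share the reference gene space")
    nn = NearestNeighbors(n_neighbors=min(emb.knn, Xr.shape[0])).fit(Xr)
    dist, idx = nn.kneighbors(Xn)
    Kn = np.zeros((Xn.shape[0], Xr.shape[0]))
    w = np.exp(-dist ** 2 / (2 * emb.sigma ** 2))
    np.put_along_axis(Kn, idx, w, axis=1)
    if emb.ref_kth_dist is not None and Xn.shape[0] * Xr.shape[0] <= 50_000_000:
        # mirror the union symmetrisation: also keep edges where the
        # reference cell would list the new cell among its k neighbours
        from scipy.spatial.distance import cdist
        D_full = cdist(Xn, Xr)
        reverse = D_full <= emb.ref_kth_dist[None, :]
        Kn = np.where(reverse | (Kn > 0),
                      np.exp(-np.square(D_full) / (2 * emb.sigma ** 2)), Kn)

    placed = Kn.sum(axis=1) > 0
    if not placed.all():
        logger.warning("%d cells have no kernel mass to the reference; "
                       "not placed", int((~placed).sum()))
    q_new = Kn.sum(axis=1)
    Kt = Kn / np.where(q_new > 0, q_new, 1.0)[:, None] / emb.density_q[None, :]
    row_sum = Kt.sum(axis=1)
    P = Kt / np.where(row_sum > 0, row_sum, 1.0)[:, None]
    coords = P @ emb.components / emb.eigenvalues[None, :]
    coords[~placed] = np.nan
    return coords, placed
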