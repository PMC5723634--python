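import numpy as np
import pytest
import scipy.sparse as sp

from sctrails import preprocess, synthetic
from sctrails.containers import CountMatrix


def make_count_matrix(counts, samples=None, barcodes=None, gene_ids=None):
    """Wrap a dense count array into a CountMatrix with minimal annotations."""
    counts = np.asarray(counts)
    n, g = counts.shape
    if samples is None:
        samples = ["S1"] * n
    samples = np.asarray(samples, object)
    if barcodes is None:
        barcodes = np.array([f"BC{i:05d}" for i in range(n)], object)
    cell_ids = np.array([f"{b}-{s}" for b, s in zip(barcodes, samples)], object)
    if gene_ids is None:
        gene_ids = np.array([f"g{j}" for j in range(g)], object)
    return CountMatrix(
        counts=sp.csr_matrix(counts), cell_ids=cell_ids,
        raw_barcodes=np.asarray(barcodes, object),
        gene_ids=np.asarray(gene_ids, object), sample_of_cell=samples,
        timepoint_of_cell=samples.copy())


def nb_counts(rng, mu, n_cells, phi=0.1):
    """Gamma-Poisson draws, one row per cell."""
    lam = rng.gamma(1.0 / phi, phi * np.asarray(mu)[None, :] * np.ones((n_cells, 1)))
    return rng.poisson(lam)


def bifurcation_config(seed, n_shared=150, n_branch=300, **kw):
    """Pure 2000-cell planted bifurcation (no discrete clusters, no artifacts)."""
    cfg = synthetic.default_config(seed=seed)
    cfg.clusters = []
    cfg.trajectory.fraction = 1.0
    cfg.trajectory.n_shared_genes = n_shared
    cfg.trajectory.n_branch_genes = n_branch
    cfg.artifacts = synthetic.ArtifactSpec()
    for k, v in kw.items():
        setattr(cfg.trajectory, k, v)
    return cfg


def normalized_bifurcation(seed, **kw):
    cm, truth = synthetic.simulate_dataset(bifurcation_config(seed, **kw))
    sf = preprocess.compute_size_factors(cm)
    nm = preprocess.log_normalize(cm, sf)
    return cm, truth, nm


@pytest.fixture(scope="session")
def small_sim():
    """A modest two-sample dataset with every artifact class planted."""
    cfg = synthetic.default_config(seed=11)
    cfg.n_cells_per_sample = 400
    cfg.n_genes = 600
    cfg.trajectory.n_shared_genes = 60
    cfg.trajectory.n_branch_genes = 120
    cm, truth = synthetic.simulate_dataset(cfg)
    return cm, truth


@pytest.fixture(scope="session")
def bifurcation_nm():
    """Session-wide normalized 2000-cell bifurcation (seed 0)."""
    return normalized_bifurcation(0)
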