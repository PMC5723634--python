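"""Synthetic droplet scRNA-seq generator with complete ground truth.

Emulates the statistical structure the downstream analysis assumes: several
samples of UMI counts with negative-binomial noise, discrete cell
populations (e.g. basal-like vs luminal-like) with planted marker genes, a
continuous bifurcating trajectory with shared-direction and branch-specific
genes, mitochondrial genes, and planted artifacts (low-quality cells,
high-mitochondrial cells, a doublet cluster formed as the average of two
parent populations, and barcodes duplicated across samples).

The count model is gene ~ NB(mean = depth_c * p_g(state), dispersion phi),
sampled as a gamma-Poisson mixture; p_g(state) is the relative expression
profile of the cell's state. Trajectory genes follow normalised logistic
curves of pseudotime, so a gene with planted amplitude ``a`` moves exactly
``a`` log2 units between pseudotime 0 and 1 on the branch where it is
active, and monotonically in between.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import ConfigurationError, CountMatrix

_BASES = np.array(list("ACGT"))


@dataclass
class ClusterSpec:
    cluster_id: str
    proportion: float
    n_marker_genes: int = 20
    marker_log2fc: float = 2.0


@dataclass
class TrajectorySpec:
    """A bifurcating continuum: trunk until ``branch_point``, then two branches."""

    fraction: float = 0.5            # fraction of all cells on the continuum
    branch_point: float = 0.4        # tau_b, in (0, 1)
    branch_proportions: Tuple[float, float] = (0.5, 0.5)
    n_shared_genes: int = 150        # half up-, half down-regulated
    n_branch_genes: int = 300        # half specific to each branch
    shared_amplitude: float = 1.5    # log2 units over the full pseudotime range
    branch_amplitude: float = 2.5


@dataclass
class DoubletClusterSpec:
    parents: Tuple[str, str] = ("", "")
    frequency: float = 0.0           # within-sample frequency of the doublet cluster


@dataclass
class ArtifactSpec:
    low_quality_fraction: float = 0.0
    low_quality_scale: float = 0.05  # binomial downsampling rate for depth
    high_mito_fraction: float = 0.0
    high_mito_level: float = 0.1     # target mitochondrial UMI fraction
    doublet_cluster: Optional[DoubletClusterSpec] = None
    n_shared_barcodes: int = 0

    def is_null(self) -> bool:
        return (self.low_quality_fraction == 0 and self.high_mito_fraction == 0
                and self.n_shared_barcodes == 0
                and (self.doublet_cluster is None
                     or self.doublet_cluster.frequency == 0))


@dataclass
class SimConfig:
    n_cells_per_sample: int = 1000
    n_genes: int = 1500
    n_mito_genes: int = 10
    samples: List[Tuple[str, str]] = field(
        default_factory=lambda: [("NP1", "NP"), ("G1", "G")])
    clusters: List[ClusterSpec] = field(default_factory=list)
    trajectory: Optional[TrajectorySpec] = None
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    nb_dispersion: float = 0.1
    mean_library_size: float = 5000.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.n_cells_per_sample <= 0:
            raise ConfigurationError("n_cells_per_sample must be positive")
        if self.n_mito_genes < 0 or self.n_mito_genes >= self.n_genes:
            raise ConfigurationError("n_mito_genes must be in [0, n_genes)")
        if not self.samples:
            raise ConfigurationError("samples must be non-empty")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.mean_library_size <= 0:
            raise ConfigurationError("mean_library_size must be positive")
        frac = self.trajectory.fraction if self.trajectory else 0.0
        if not 0 <= frac <= 1:
            raise ConfigurationError("trajectory.fraction must be in [0, 1]")
        if self.trajectory and not 0 < self.trajectory.branch_point < 1:
            raise ConfigurationError("trajectory.branch_point must be in (0, 1)")
        psum = sum(c.proportion for c in self.clusters)
        if psum > 1 + 1e-9:
            raise ConfigurationError("clusters: proportions must sum to <= 1")
        if frac == 0 and not self.clusters:
            raise ConfigurationError("clusters: need at least one population or a trajectory")
        art = self.artifacts
        for name in ("low_quality_fraction", "high_mito_fraction"):
            v = getattr(art, name)
            if not 0 <= v < 1:
                raise ConfigurationError(f"artifacts.{name} must be in [0, 1)")
        if art.doublet_cluster is not None and art.doublet_cluster.frequency > 0:
            if not art.doublet_cluster.frequency < 1:
                raise ConfigurationError("artifacts.doublet_cluster.frequency must be < 1")
            ids = {c.cluster_id for c in self.clusters}
            for p in art.doublet_cluster.parents:
                if p not in ids:
                    raise ConfigurationError(
                        f"artifacts.doublet_cluster: parent {p!r} not in clusters")

    def snapshot(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Every planted fact needed for parameter-recovery tests.

    ``cells``: indexed by cell id — population, pseudotime (NaN off the
    continuum), branch in {A, B, trunk} or empty, artifact flags.
    ``genes``: indexed by gene id — is_mito, marker_of, trajectory_class in
    {none, shared_up, shared_down, branchA_specific, branchB_specific},
    amplitude, logistic midpoint/width, baseline relative expression.
    ``state_profiles``: genes x discrete-population relative profiles.
    """

    cells: pd.DataFrame
    genes: pd.DataFrame
    state_profiles: pd.DataFrame
    config: dict
    seed: int

    def validate_against(self, cm: CountMatrix) -> None:
        if len(self.cells) != cm.n_cells or len(self.genes) != cm.n_genes:
            raise ValueError("truth dimensions do not match the count matrix")
        cont = self.cells["pseudotime"].notna()
        tau = (self.config.get("trajectory") or {}).get("branch_point", np.nan)
        if cont.any() and np.isfinite(tau):
            trunk = cont & (self.cells["pseudotime"] < tau)
            if not (self.cells.loc[trunk, "branch"] == "trunk").all():
                raise ValueError("continuum cells before the branch point must be trunk")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def activation_curve(t, midpoint: float, width: float) -> np.ndarray:
    """Normalised logistic in pseudotime: exactly 0 at t=0 and 1 at t=1,
    strictly increasing in between."""
    t = np.asarray(t, dtype=float)
    lo = _logistic((0.0 - midpoint) / width)
    hi = _logistic((1.0 - midpoint) / width)
    return (_logistic((t - midpoint) / width) - lo) / (hi - lo)


def trajectory_means(pseudotime, branch: str, gene_programs: pd.DataFrame) -> np.ndarray:
    """Per-gene relative mean vector at a pseudotime on a branch.

    ``branch`` is one of {"A", "B", "trunk"}. Shared-direction genes move on
    every branch; a branch-specific gene moves only on its own branch, so at
    pseudotime 0 all branches coincide.
    """
    if branch not in ("A", "B", "trunk"):
        raise ValueError(f"unknown branch label {branch!r}")
    base = gene_programs["base_rel"].to_numpy(float)
    cls = gene_programs["trajectory_class"].to_numpy(object)
    amp = gene_programs["amplitude"].to_numpy(float)
    mid = gene_programs["midpoint"].to_numpy(float)
    wid = gene_programs["width"].to_numpy(float)
    log2fc = np.zeros(len(gene_programs))
    active = np.isin(cls, ["shared_up", "shared_down"])
    if branch == "A":
        active = active | (cls == "branchA_specific")
    elif branch == "B":
        active = active | (cls == "branchB_specific")
    if active.any():
        idx = np.flatnonzero(active)
        t = float(pseudotime)
        lo = _logistic((0.0 - mid[idx]) / wid[idx])
        hi = _logistic((1.0 - mid[idx]) / wid[idx])
        curves = (_logistic((t - mid[idx]) / wid[idx]) - lo) / (hi - lo)
        sign = np.where(cls[idx] == "shared_down", -1.0, 1.0)
        log2fc[idx] = sign * amp[idx] * curves
    return base * np.exp2(log2fc)


def _random_barcodes(rng: np.random.Generator, n: int, length: int = 12) -> np.ndarray:
    seen, out = set(), []
    while len(out) < n:
        bc = "".join(rng.choice(_BASES, size=length))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return np.array(out, dtype=object)


def _build_gene_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_genes
    gene_ids = np.array(
        [f"mt-{i+1:03d}" for i in range(cfg.n_mito_genes)]
        + [f"gene{i+1:05d}" for i in range(n - cfg.n_mito_genes)], dtype=object)
    is_mito = np.array([g.startswith("mt-") for g in gene_ids])

    base = rng.lognormal(mean=0.0, sigma=1.5, size=n)
    # Mitochondrial transcripts are few but highly expressed: give them a
    # combined baseline share of ~2.5% of the library.
    if cfg.n_mito_genes:
        non_mito_total = base[~is_mito].sum()
        base[is_mito] = rng.lognormal(0.0, 0.3, cfg.n_mito_genes)
        base[is_mito] *= 0.025 * non_mito_total / (0.975 * base[is_mito].sum())
    base = base / base.sum()

    genes = pd.DataFrame({
        "gene_id": gene_ids, "is_mito": is_mito, "marker_of": "",
        "trajectory_class": "none", "amplitude": 0.0,
        "midpoint": 0.5, "width": 0.15, "base_rel": base,
    }).set_index("gene_id")

    assignable = np.flatnonzero(~is_mito)
    perm = rng.permutation(assignable)
    taken = np.zeros(n, dtype=bool)
    # trajectory programmes go on genes expressed well enough that the
    # planted log2 amplitude survives the log(count+1) compression
    expressed = base * cfg.mean_library_size >= 1.0

    def take(k: int, require_expressed: bool = False) -> np.ndarray:
        pool = [i for i in perm
                if not taken[i] and (expressed[i] or not require_expressed)]
        if len(pool) < k:
            raise ConfigurationError(
                "n_genes too small for the requested marker/trajectory genes")
        out = np.asarray(pool[:k])
        taken[out] = True
        return out

    for cl in cfg.clusters:
        idx = take(cl.n_marker_genes)
        genes.iloc[idx, genes.columns.get_loc("marker_of")] = cl.cluster_id

    traj = cfg.trajectory
    if traj is not None and traj.fraction > 0:
        n_up = traj.n_shared_genes // 2
        n_down = traj.n_shared_genes - n_up
        n_a = traj.n_branch_genes // 2
        n_b = traj.n_branch_genes - n_a
        for klass, k, amp in [("shared_up", n_up, traj.shared_amplitude),
                              ("shared_down", n_down, traj.shared_amplitude),
                              ("branchA_specific", n_a, traj.branch_amplitude),
                              ("branchB_specific", n_b, traj.branch_amplitude)]:
            idx = take(k, require_expressed=True)
            genes.iloc[idx, genes.columns.get_loc("trajectory_class")] = klass
            genes.iloc[idx, genes.columns.get_loc("amplitude")] = amp
            if klass.startswith("shared"):
                mids = rng.uniform(0.05, 0.95, k)
            else:
                # branch genes switch on after the branch point
                tb = traj.branch_point
                mids = rng.uniform(tb + 0.05 * (1 - tb), tb + 0.9 * (1 - tb), k)
            genes.iloc[idx, genes.columns.get_loc("midpoint")] = mids
            genes.iloc[idx, genes.columns.get_loc("width")] = rng.uniform(0.08, 0.15, k)
    return genes


def _state_profiles(cfg: SimConfig, genes: pd.DataFrame) -> pd.DataFrame:
    """Relative expression profile of each discrete population."""
    profiles = {}
    base = genes["base_rel"].to_numpy(float)
    for cl in cfg.clusters:
        p = base.copy()
        mask = (genes["marker_of"] == cl.cluster_id).to_numpy()
        p[mask] *= 2.0 ** cl.marker_log2fc
        profiles[cl.cluster_id] = p / p.sum()
    return pd.DataFrame(profiles, index=genes.index)


def expected_mean_profile(truth: SyntheticTruth, cell_id: str) -> np.ndarray:
    """Relative expected expression profile of one cell, reconstructed from truth."""
    row = truth.cells.loc[cell_id]
    pop = row["population"]
    if pop == "doublet":
        parents = truth.config["artifacts"]["doublet_cluster"]["parents"]
        p = truth.state_profiles[list(parents)].mean(axis=1).to_numpy()
        return p / p.sum()
    if pop == "continuum":
        p = trajectory_means(row["pseudotime"], row["branch"], truth.genes)
        return p / p.sum()
    p = truth.state_profiles[pop].to_numpy(float)
    return p / p.sum()


def simulate_dataset(config: SimConfig) -> Tuple[CountMatrix, SyntheticTruth]:
    """Draw a full multi-sample dataset and its ground truth.

    Deterministic: identical (config, seed) gives bit-identical counts.
    Artifacts configured in ``config.artifacts`` are applied through
    :func:`inject_artifacts` after the clean draw.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _build_gene_table(config, rng)
    profiles = _state_profiles(config, genes)

    traj = config.trajectory
    p_cont = traj.fraction if traj else 0.0
    cl_ids = [c.cluster_id for c in config.clusters]
    cl_props = np.array([c.proportion for c in config.clusters], float)
    if cl_props.sum() > 0:
        cl_props = cl_props / cl_props.sum() * (1 - p_cont)
    state_names = ["continuum"] + cl_ids
    state_probs = np.array([p_cont] + list(cl_props))
    state_probs = state_probs / state_probs.sum()

    rows = []
    for sample_id, timepoint in config.samples:
        barcodes = _random_barcodes(rng, config.n_cells_per_sample)
        states = rng.choice(len(state_names), size=config.n_cells_per_sample,
                            p=state_probs)
        for i in range(config.n_cells_per_sample):
            state = state_names[states[i]]
            t, branch = np.nan, ""
            if state == "continuum":
                t = rng.uniform(0.0, 1.0)
                if t < traj.branch_point:
                    branch = "trunk"
                else:
                    pa, pb = traj.branch_proportions
                    branch = "A" if rng.uniform() < pa / (pa + pb) else "B"
            rows.append((f"{barcodes[i]}-{sample_id}", barcodes[i], sample_id,
                         timepoint, state, t, branch))
    cells = pd.DataFrame(
        rows, columns=["cell_id", "raw_barcode", "sample", "timepoint",
                       "population", "pseudotime", "branch"]).set_index("cell_id")
    cells["is_low_quality"] = False
    cells["is_high_mito"] = False
    cells["is_doublet_cluster_member"] = False
    cells["shared_barcode"] = False

    n_cells = len(cells)
    mean_mat = np.empty((n_cells, config.n_genes))
    for i, (cid, row) in enumerate(cells.iterrows()):
        if row["population"] == "continuum":
            p = trajectory_means(row["pseudotime"], row["branch"], genes)
            mean_mat[i] = p / p.sum()
        else:
            mean_mat[i] = profiles[row["population"]].to_numpy()

    depth = config.mean_library_size * rng.lognormal(0.0, 0.3, n_cells)
    mu = mean_mat * depth[:, None]
    phi = config.nb_dispersion
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
    counts = rng.poisson(lam).astype(np.int64)

    cm = CountMatrix(
        counts=sp.csr_matrix(counts),
        cell_ids=cells.index.to_numpy(object),
        raw_barcodes=cells["raw_barcode"].to_numpy(object),
        gene_ids=genes.index.to_numpy(object),
        sample_of_cell=cells["sample"].to_numpy(object),
        timepoint_of_cell=cells["timepoint"].to_numpy(object),
    )
    truth = SyntheticTruth(
        cells=cells, genes=genes, state_profiles=profiles,
        config=config.snapshot(), seed=config.seed)

    cm, truth = inject_artifacts(cm, truth, config.artifacts,
                                 seed=int(rng.integers(2 ** 31)))
    truth.validate_against(cm)
    return cm, truth


def inject_artifacts(cm: CountMatrix, truth: SyntheticTruth,
                     artifact_spec: ArtifactSpec,
                     seed: int = 0) -> Tuple[CountMatrix, SyntheticTruth]:
    """Plant QC artifacts into a clean dataset.

    Low-quality cells are binomially downsampled (depth attacked, composition
    preserved); high-mito cells get extra mitochondrial UMIs up to the target
    fraction; doublet-cluster members are redrawn from the arithmetic mean of
    their parents' expected profiles with elevated depth; shared barcodes are
    copied verbatim between the first two samples.
    """
    if artifact_spec.is_null():
        return cm, truth

    rng = np.random.default_rng(seed)
    counts = cm.counts.toarray().astype(np.int64)
    cells = truth.cells.copy()
    raw_barcodes = cm.raw_barcodes.copy()
    n_cells = cm.n_cells
    phi = truth.config["nb_dispersion"]

    dbl = artifact_spec.doublet_cluster
    if dbl is not None and dbl.frequency > 0:
        for p in dbl.parents:
            if p not in truth.state_profiles.columns:
                raise ConfigurationError(
                    f"doublet parent {p!r} not among simulated clusters")
        prof = truth.state_profiles[list(dbl.parents)].mean(axis=1).to_numpy()
        prof = prof / prof.sum()
        for sample in pd.unique(cells["sample"]):
            in_sample = np.flatnonzero((cells["sample"] == sample).to_numpy())
            k = int(round(dbl.frequency * len(in_sample)))
            pool = [i for i in in_sample
                    if cells.iloc[i]["population"] in dbl.parents]
            chosen = rng.choice(pool, size=min(k, len(pool)), replace=False)
            for i in chosen:
                depth = 1.8 * counts[i].sum()  # doublets carry more molecules
                mu = prof * depth
                counts[i] = rng.poisson(rng.gamma(1.0 / phi, phi * mu))
            cells.iloc[chosen, cells.columns.get_loc("population")] = "doublet"
            cells.iloc[chosen, cells.columns.get_loc("pseudotime")] = np.nan
            cells.iloc[chosen, cells.columns.get_loc("branch")] = ""
            cells.iloc[chosen, cells.columns.get_loc("is_doublet_cluster_member")] = True

    eligible = np.flatnonzero(~cells["is_doublet_cluster_member"].to_numpy())
    if artifact_spec.low_quality_fraction > 0:
        k = int(round(artifact_spec.low_quality_fraction * n_cells))
        lowq = rng.choice(eligible, size=min(k, len(eligible)), replace=False)
        counts[lowq] = rng.binomial(counts[lowq], artifact_spec.low_quality_scale)
        cells.iloc[lowq, cells.columns.get_loc("is_low_quality")] = True

    if artifact_spec.high_mito_fraction > 0:
        mito_idx = np.flatnonzero(truth.genes["is_mito"].to_numpy())
        if len(mito_idx) == 0:
            raise ConfigurationError("high_mito_fraction set but no mito genes")
        pool = np.flatnonzero(~(cells["is_doublet_cluster_member"]
                                | cells["is_low_quality"]).to_numpy())
        k = int(round(artifact_spec.high_mito_fraction * n_cells))
        hm = rng.choice(pool, size=min(k, len(pool)), replace=False)
        f = artifact_spec.high_mito_level
        w = truth.genes["base_rel"].to_numpy()[mito_idx]
        w = w / w.sum()
        for i in hm:
            total, mito = counts[i].sum(), counts[i, mito_idx].sum()
            extra = int(np.ceil(max(0.0, (f * total - mito) / (1 - f))))
            if extra > 0:
                counts[i, mito_idx] += rng.multinomial(extra, w)
        cells.iloc[hm, cells.columns.get_loc("is_high_mito")] = True

    if artifact_spec.n_shared_barcodes > 0:
        samples = list(pd.unique(cells["sample"]))
        if len(samples) < 2:
            raise ConfigurationError("n_shared_barcodes needs >= 2 samples")
        s1 = np.flatnonzero((cells["sample"] == samples[0]).to_numpy())
        s2 = np.flatnonzero((cells["sample"] == samples[1]).to_numpy())
        k = artifact_spec.n_shared_barcodes
        src = rng.choice(s1, size=k, replace=False)
        dst = rng.choice(s2, size=k, replace=False)
        for a, b in zip(src, dst):
            raw_barcodes[b] = raw_barcodes[a]
            cells.iloc[[a, b], cells.columns.get_loc("shared_barcode")] = True
    cells["raw_barcode"] = raw_barcodes

    new_ids = np.array([f"{rb}-{s}" for rb, s in
                        zip(raw_barcodes, cells["sample"])], dtype=object)
    # barcode copying may collide with an existing id; disambiguate determin.
    seen: dict = {}
    for i, cid in enumerate(new_ids):
        if cid in seen:
            new_ids[i] = f"{cid}.{seen[cid]}"
            seen[cid] += 1
        else:
            seen[cid] = 1
    cells.index = pd.Index(new_ids, name="cell_id")

    cm2 = CountMatrix(
        counts=sp.csr_matrix(counts), cell_ids=new_ids,
        raw_barcodes=raw_barcodes, gene_ids=cm.gene_ids,
        sample_of_cell=cm.sample_of_cell, timepoint_of_cell=cm.timepoint_of_cell)
    truth2 = SyntheticTruth(cells=cells, genes=truth.genes,
                            state_profiles=truth.state_profiles,
                            config=truth.config, seed=truth.seed)
    return cm2, truth2


def default_config(seed: int = 0) -> SimConfig:
    """The reference study conditions used by the end-to-end pipeline run:
    two samples of 1000 cells, 1500 genes, a basal-like population plus a
    bifurcating luminal continuum, and every artifact class planted."""
    return SimConfig(
        n_cells_per_sample=1000,
        n_genes=1500,
        n_mito_genes=10,
        samples=[("NP1", "NP"), ("G1", "G")],
        clusters=[
            ClusterSpec("Basal", 0.30, n_marker_genes=40, marker_log2fc=2.5),
            ClusterSpec("LumMature", 0.70, n_marker_genes=40, marker_log2fc=2.5),
        ],
        trajectory=TrajectorySpec(
            fraction=0.55, branch_point=0.4, branch_proportions=(0.5, 0.5),
            n_shared_genes=150, n_branch_genes=300,
            shared_amplitude=1.5, branch_amplitude=2.5),
        artifacts=ArtifactSpec(
            low_quality_fraction=0.05, low_quality_scale=0.05,
            high_mito_fraction=0.03, high_mito_level=0.10,
            doublet_cluster=DoubletClusterSpec(parents=("Basal", "LumMature"),
                                               frequency=0.04),
            n_shared_barcodes=5),
        nb_dispersion=0.1,
        mean_library_size=5000.0,
        seed=seed,
    )
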