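"""End-to-end orchestration: simulate/read -> QC -> normalise -> cluster ->
markers -> trajectory -> pseudotime DE, with TSV outputs and a JSON manifest.

Every stage writes its tables under the output directory; the manifest
records parameters, seeds and input hashes so a rerun from the same
manifest reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import clustering, diffexpr, preprocess, pseudotime_de, synthetic, trajectory
from .containers import ConfigurationError
from .io import read_counts_mtx, write_counts_mtx, write_json, write_tsv

logger = logging.getLogger(__name__)

KNOWN_SECTIONS = {"simulate", "input", "qc", "hvg", "cluster", "de",
                  "trajectory", "ptde", "seed", "log_level"}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def validate_config(config: dict) -> dict:
    unknown = set(config) - KNOWN_SECTIONS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    cfg = {k: config.get(k) for k in KNOWN_SECTIONS}
    cfg["seed"] = int(config.get("seed", 0))
    for section in ("qc", "hvg", "cluster", "de", "trajectory", "ptde"):
        cfg[section] = dict(config.get(section) or {})
    if cfg["simulate"] is None and cfg["input"] is None:
        raise ConfigurationError("config needs either 'simulate' or 'input'")
    return cfg


def sim_config_from_dict(d: dict, seed: int) -> synthetic.SimConfig:
    d = dict(d)
    clusters = [synthetic.ClusterSpec(**c) for c in d.pop("clusters", [])]
    traj = d.pop("trajectory", None)
    traj = synthetic.TrajectorySpec(**{**traj, "branch_proportions":
                                       tuple(traj.get("branch_proportions", (0.5, 0.5)))}) \
        if traj else None
    art = d.pop("artifacts", None)
    if art:
        art = dict(art)
        dbl = art.pop("doublet_cluster", None)
        if dbl:
            dbl = synthetic.DoubletClusterSpec(parents=tuple(dbl["parents"]),
                                               frequency=dbl.get("frequency", 0.0))
        art = synthetic.ArtifactSpec(**art, doublet_cluster=dbl)
    else:
        art = synthetic.ArtifactSpec()
    samples = [tuple(s) for s in d.pop("samples", [("NP1", "NP"), ("G1", "G")])]
    return synthetic.SimConfig(samples=samples, clusters=clusters,
                               trajectory=traj, artifacts=art,
                               seed=d.pop("seed", seed), **d)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: dict, outdir, skip: Sequence[str] = ()) -> Path:
    """Run the full analysis chain and return the output directory.

    ``skip`` names stages to leave out ("trajectory" also skips the
    downstream pseudotime DE). A stage failure raises :class:`StageError`
    naming the stage; outputs of earlier stages persist.
    """
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    manifest = {"config": {k: cfg[k] for k in sorted(KNOWN_SECTIONS)
                           if k not in ("input",)},
                "input": str(cfg["input"]) if cfg["input"] else None,
                "seed": seed, "stages": []}
    stage = "setup"
    try:
        if cfg["simulate"] is not None:
            stage = "simulate"
            if cfg["simulate"]:
                sim_cfg = sim_config_from_dict(cfg["simulate"], seed)
            else:  # empty section: the reference study configuration
                sim_cfg = synthetic.default_config(seed=seed)
            cm, truth = synthetic.simulate_dataset(sim_cfg)
            write_counts_mtx(cm, outdir / "simulated")
            write_tsv(truth.cells, outdir / "simulated" / "truth_cells.tsv")
            write_tsv(truth.genes, outdir / "simulated" / "truth_genes.tsv")
            write_json(sim_cfg.snapshot(), outdir / "simulated" / "sim_config.json")
            manifest["stages"].append("simulate")
        else:
            stage = "read"
            cm = read_counts_mtx(cfg["input"])
            mtx = Path(cfg["input"]) / "matrix.mtx"
            if mtx.exists():
                manifest["input_sha256"] = _hash_file(mtx)

        stage = "qc"
        passed, report = preprocess.apply_qc(cm, **cfg["qc"])
        write_tsv(report.cells, outdir / "qc_report.tsv")
        write_tsv(report.sample_thresholds, outdir / "qc_thresholds.tsv")
        manifest["stages"].append("qc")
        manifest["n_cells_pass"] = int(passed.n_cells)

        stage = "normalise"
        sf = preprocess.compute_size_factors(passed)
        nm = preprocess.log_normalize(passed, sf)
        stats = preprocess.fit_mean_variance_trend(nm)
        hvgs = preprocess.select_hvgs(stats, n_cells=nm.n_cells, **cfg["hvg"])
        write_tsv(hvgs, outdir / "hvg_table.tsv")
        write_tsv(pd.DataFrame({"size_factor": sf},
                               index=pd.Index(nm.cell_ids, name="cell_id")),
                  outdir / "size_factors.tsv")
        manifest["stages"].append("normalise")
        hvg_idx = np.flatnonzero(hvgs["is_hvg"].to_numpy())
        if hvg_idx.size < 2:
            raise ValueError("fewer than 2 HVGs selected; cannot cluster")
        hvg_expr = nm.logexpr[:, hvg_idx]
        manifest["n_hvgs"] = int(hvg_idx.size)

        stage = "cluster"
        ccfg = cfg["cluster"]
        assignment = clustering.two_step_cluster(
            hvg_expr, k=ccfg.get("k", 20), k_max=ccfg.get("k_max", 6),
            B=ccfg.get("B", 50), seed=seed, cell_ids=nm.cell_ids)
        final, history = clustering.merge_similar_clusters(
            assignment.cells["refined"].to_numpy(), passed.counts, sf,
            min_de=ccfg.get("min_de", 10), p_thresh=ccfg.get("p_thresh", 0.01),
            lfc=ccfg.get("lfc", 1.0), floor=cfg["de"].get("floor", 0.1))
        assignment.cells["final"] = final
        assignment.merge_history = history
        contam = clustering.flag_contaminant_clusters(
            final, nm.logexpr, nm.gene_ids,
            marker_config=ccfg.get("marker_config"),
            margin=ccfg.get("contaminant_margin", 1.0))
        doublets = clustering.flag_doublet_clusters(
            final, passed.counts, passed.sample_of_cell,
            max_rate=ccfg.get("doublet_max_rate", 0.07),
            rho_min=ccfg.get("doublet_rho_min", 0.9))
        info = contam.join(doublets, how="outer")
        assignment.cluster_info = info
        write_tsv(assignment.cells, outdir / "cluster_labels.tsv")
        write_tsv(info, outdir / "cluster_flags.tsv")
        write_tsv(pd.DataFrame(history), outdir / "merge_history.tsv",
                  index=False)
        if info.index.size >= 2:
            _, _, newick = clustering.cluster_dendrogram(final, nm.logexpr)
            (outdir / "cluster_dendrogram.nwk").write_text(newick + "\n")
        manifest["stages"].append("cluster")
        manifest["n_clusters_final"] = int(len(set(final)))

        stage = "markers"
        if "markers" not in skip and len(set(final)) >= 2:
            tables = diffexpr.find_markers(
                final, nm.logexpr, passed.counts, sf, nm.gene_ids,
                min_median=cfg["de"].get("marker_min_median", 1.0))
            rows = [tab.assign(cluster=cl) for cl, tab in tables.items()
                    if len(tab)]
            if rows:
                write_tsv(pd.concat(rows), outdir / "markers.tsv")
            manifest["stages"].append("markers")

        if "trajectory" not in skip:
            stage = "trajectory"
            tcfg = cfg["trajectory"]
            keep = np.ones(nm.n_cells, dtype=bool)
            if tcfg.get("exclude_flagged", True):
                bad = set(info.index[(info.get("is_doublet", False) == True)  # noqa: E712
                                     | (info.get("contaminant", "") != "")])
                keep &= ~np.isin(final, list(bad))
            tps = tcfg.get("timepoints")
            if tps:
                keep &= np.isin(nm.timepoint_of_cell, tps)
            excl = tcfg.get("exclude_clusters")
            if excl:
                keep &= ~np.isin(final, excl)
            idx = np.flatnonzero(keep)
            if tcfg.get("restrict_to_largest_component", True):
                sub = trajectory.largest_connected_component(
                    hvg_expr[idx], knn=tcfg.get("knn", 30))
                idx = idx[sub]
            emb, ta = trajectory.infer_trajectory(
                hvg_expr[idx], n_components=tcfg.get("n_components", 10),
                knn=tcfg.get("knn", 30), cell_ids=nm.cell_ids[idx])
            emb_df = pd.DataFrame(
                emb.components,
                index=pd.Index(emb.cell_ids, name="cell_id"),
                columns=[f"DC{i + 1}" for i in range(emb.n_components)])
            write_tsv(emb_df, outdir / "diffusion_components.tsv")
            write_tsv(ta.cells, outdir / "trajectory.tsv")
            write_json({"root": ta.root, "tip1": ta.tip1, "tip2": ta.tip2,
                        "eigenvalues": emb.eigenvalues.tolist()},
                       outdir / "trajectory_anchors.json")
            manifest["stages"].append("trajectory")

            if "ptde" not in skip:
                stage = "ptde"
                pcfg = cfg["ptde"]
                sub_nm = dataclasses.replace(
                    nm, logexpr=nm.logexpr[idx], size_factors=nm.size_factors[idx],
                    cell_ids=nm.cell_ids[idx],
                    sample_of_cell=nm.sample_of_cell[idx],
                    timepoint_of_cell=nm.timepoint_of_cell[idx])
                tt = pseudotime_de.test_branch_genes(
                    sub_nm, ta, alpha=pcfg.get("alpha", 0.01),
                    min_amplitude=pcfg.get("min_amplitude", 0.5),
                    df=pcfg.get("df", 3),
                    gradient_alpha=pcfg.get("gradient_alpha", 0.01))
                write_tsv(tt.per_branch, outdir / "trend_table.tsv", index=False)
                write_tsv(tt.per_gene, outdir / "gene_classes.tsv")
                for branch in tt.grids:
                    if len(pseudotime_de.per_branch_significant(tt, branch)) >= 10:
                        order = pseudotime_de.cluster_trends(
                            tt, branch,
                            min_cluster_size=pcfg.get("min_cluster_size", 5))
                        write_tsv(order, outdir / f"trend_clusters_{branch}.tsv")
                manifest["stages"].append("ptde")

        manifest["n_cells_input"] = int(cm.n_cells)
        write_json(manifest, outdir / "manifest.json")
        return outdir
    except Exception as exc:  # annotate with the failing stage
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
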