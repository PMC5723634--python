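"""Reading and writing the 10x-style Matrix-Market triplet layout.

A count directory contains ``matrix.mtx`` (genes as rows, cells as columns),
``genes.tsv`` and ``barcodes.tsv``, each optionally gzipped, mirroring the
CellRanger triplet dialect. An optional ``cell_metadata.tsv`` carries the
raw barcode, sample and time-point per cell; without it the sample label is
parsed from the barcode suffix after the last ``-``.
"""

from __future__ import annotations

import gzip
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix


def _find(dirpath: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dirpath / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {dirpath}")


def _read_lines(path: Path) -> list:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_counts_mtx(dirpath) -> CountMatrix:
    """Read a 10x triplet directory into a cells x genes CountMatrix.

    The MTX file stores genes as rows; it is transposed on read. Entries
    must be integral. Raises on any dimension mismatch between the matrix
    header and the sidecar files.
    """
    dirpath = Path(dirpath)
    mtx_path = _find(dirpath, "matrix.mtx")
    if mtx_path.suffix == ".gz":
        with gzip.open(mtx_path, "rb") as fh:
            mat = scipy.io.mmread(fh)
    else:
        mat = scipy.io.mmread(str(mtx_path))
    mat = sp.csr_matrix(mat.T)  # cells x genes

    genes = [line.split("\t")[0] for line in _read_lines(_find(dirpath, "genes.tsv"))]
    barcodes = [line.split("\t")[0] for line in _read_lines(_find(dirpath, "barcodes.tsv"))]
    if mat.shape[1] != len(genes):
        raise ValueError(
            f"matrix has {mat.shape[1]} genes but genes.tsv lists {len(genes)}")
    if mat.shape[0] != len(barcodes):
        raise ValueError(
            f"matrix has {mat.shape[0]} cells but barcodes.tsv lists {len(barcodes)}")
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise ValueError("matrix entries must be integer UMI counts")
    mat.data = np.round(mat.data).astype(np.int64)

    meta_path = None
    for name in ("cell_metadata.tsv", "cell_metadata.tsv.gz"):
        if (dirpath / name).exists():
            meta_path = dirpath / name
            break
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("cell_id")
        meta = meta.loc[barcodes]
        raw = meta["raw_barcode"].to_numpy()
        sample = meta["sample"].to_numpy()
        timepoint = meta["timepoint"].to_numpy()
    else:
        raw, sample = [], []
        for bc in barcodes:
            stem, _, suffix = bc.rpartition("-")
            raw.append(stem if stem else bc)
            sample.append(suffix if stem else "sample1")
        raw, sample = np.array(raw, object), np.array(sample, object)
        timepoint = sample.copy()

    return CountMatrix(
        counts=mat, cell_ids=np.array(barcodes, object), raw_barcodes=raw,
        gene_ids=np.array(genes, object), sample_of_cell=sample,
        timepoint_of_cell=timepoint)


def write_counts_mtx(cm: CountMatrix, dirpath) -> None:
    """Write a CountMatrix as a triplet directory (genes as rows)."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(cm.counts.T.astype(np.int64))
    scipy.io.mmwrite(str(dirpath / "matrix.mtx"), mat, field="integer")
    with open(dirpath / "genes.tsv", "w") as fh:
        for g in cm.gene_ids:
            fh.write(f"{g}\t{g}\n")
    with open(dirpath / "barcodes.tsv", "w") as fh:
        for b in cm.cell_ids:
            fh.write(f"{b}\n")
    meta = pd.DataFrame({
        "cell_id": cm.cell_ids, "raw_barcode": cm.raw_barcodes,
        "sample": cm.sample_of_cell, "timepoint": cm.timepoint_of_cell})
    meta.to_csv(dirpath / "cell_metadata.tsv", sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    """Write a DataFrame as TSV with a fixed float format for reproducibility."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.8g")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_json(obj: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
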