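"""Readers and writers for the matrix and label formats the pipeline touches.

Supported formats: MatrixMarket coordinate (.mtx) with 10x-style
barcodes/features TSV sidecars (optionally gzipped), dense CSV, and a
labels TSV with one column per clustering.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datamodel import Clustering, CountMatrix, Embedding, PairedMultiomeDataset
from .errors import FormatError, PairingError, ValidationError

logger = logging.getLogger(__name__)


def _read_id_column(path: str | Path) -> np.ndarray:
    """First tab-separated column of a (possibly gzipped) TSV, as strings."""
    opener = gzip.open if str(path).endswith(".gz") else open
    ids = []
    with opener(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return np.asarray(ids, dtype=object)


def read_counts_mtx(
    matrix_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
    modality: str,
    orientation: str = "features_by_cells",
) -> CountMatrix:
    """Read a MatrixMarket count matrix with barcode/feature sidecars.

    The 10x convention stores matrices features x cells; the explicit
    ``orientation`` flag says which way the file on disk is oriented and
    the result is always returned cells x features.
    """
    if orientation not in ("features_by_cells", "cells_by_features"):
        raise FormatError(f"unknown orientation {orientation!r}")
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # pragma: no cover - scipy's message suffices
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}")
    mat = sp.coo_matrix(mat)
    if orientation == "features_by_cells":
        mat = mat.T
    cells = _read_id_column(barcodes_path)
    features = _read_id_column(features_path)
    n_cells, n_features = mat.shape
    if len(cells) != n_cells:
        raise FormatError(
            f"{len(cells)} barcodes for {n_cells} cells in {matrix_path}"
        )
    if len(features) != n_features:
        raise FormatError(
            f"{len(features)} features for {n_features} matrix features in {matrix_path}"
        )
    if mat.nnz and mat.data.min() < 0:
        raise ValidationError("negative entries in count matrix")
    return CountMatrix(mat.tocsr(), cells, features, modality, state="raw")


def write_counts_mtx(
    m: CountMatrix,
    matrix_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
    orientation: str = "features_by_cells",
) -> None:
    """Write a CountMatrix as .mtx + sidecars (inverse of read_counts_mtx)."""
    values = sp.coo_matrix(m.values)
    if orientation == "features_by_cells":
        values = values.T
    elif orientation != "cells_by_features":
        raise FormatError(f"unknown orientation {orientation!r}")
    scipy.io.mmwrite(str(matrix_path), values)
    Path(barcodes_path).write_text("\n".join(m.cell_ids) + "\n", encoding="utf-8")
    Path(features_path).write_text("\n".join(m.feature_ids) + "\n", encoding="utf-8")


def read_counts_csv(path: str | Path, modality: str) -> CountMatrix:
    """Dense CSV: header row = feature ids, first column = cell ids."""
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:
        raise FormatError(f"cannot parse CSV {path}: {exc}")
    body = df.to_numpy()
    if body.dtype == object or not np.issubdtype(body.dtype, np.number):
        # locate the first offending cell for the error report
        for i, row in enumerate(body):
            for j, v in enumerate(row):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"non-numeric value {v!r} at row {i + 1}, column {j + 1} of {path}"
                    )
        raise FormatError(f"non-numeric body in {path}")
    values = sp.csr_matrix(body.astype(np.float64))
    return CountMatrix(values, df.index.astype(str).to_numpy(dtype=object),
                       df.columns.astype(str).to_numpy(dtype=object),
                       modality, state="raw")


def pair(rna: CountMatrix, atac: CountMatrix) -> PairedMultiomeDataset:
    """Subset both modalities to their shared cells, in RNA order."""
    atac_index = atac.cell_index()
    shared_mask = np.array([c in atac_index for c in rna.cell_ids], dtype=bool)
    shared = rna.cell_ids[shared_mask]
    if len(shared) == 0:
        raise PairingError("no shared cell ids between RNA and ATAC")
    dropped_rna = rna.n_cells - len(shared)
    dropped_atac = atac.n_cells - len(shared)
    if dropped_rna or dropped_atac:
        logger.info("pairing dropped %d RNA cells and %d ATAC cells",
                    dropped_rna, dropped_atac)
    rna_sub = rna.subset_cells(np.flatnonzero(shared_mask))
    atac_sub = atac.subset_cells(np.array([atac_index[c] for c in shared]))
    return PairedMultiomeDataset(rna_sub, atac_sub)


def write_labels(clusterings: Sequence[Clustering], path: str | Path,
                 names: Sequence[str] | None = None) -> None:
    """Write clusterings side by side as a TSV keyed by cell_id."""
    if not clusterings:
        raise ValidationError("no clusterings to write")
    ref = clusterings[0].cell_ids
    for c in clusterings[1:]:
        if not np.array_equal(c.cell_ids, ref):
            raise ValidationError("clusterings cover different cell sets")
    if names is None:
        names = [c.source for c in clusterings]
        if len(set(names)) != len(names):
            names = [f"{c.source}_{i}" for i, c in enumerate(clusterings)]
    df = pd.DataFrame({"cell_id": ref})
    for name, c in zip(names, clusterings):
        df[name] = c.labels
    df.to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a labels TSV back into a DataFrame indexed by cell_id."""
    return pd.read_csv(path, sep="\t", index_col="cell_id")


def write_embedding_csv(emb: Embedding, path: str | Path) -> None:
    cols = {f"{emb.method}_{i + 1}": emb.coords[:, i]
            for i in range(emb.n_components)}
    pd.DataFrame({"cell_id": emb.cell_ids, **cols}).to_csv(path, index=False)


def read_embedding_csv(path: str | Path, method: str) -> Embedding:
    df = pd.read_csv(path)
    coords = df.drop(columns=["cell_id"]).to_numpy(dtype=np.float64)
    return Embedding(coords, method, df["cell_id"].astype(str).to_numpy(dtype=object))
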