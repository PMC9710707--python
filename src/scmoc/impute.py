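"""Cross-modality kNN imputation of sparse ATAC profiles.

The central idea: cell-cell similarity is estimated in the dense RNA
modality (PCA space) and each cell's ATAC profile is replaced by the
average normalized profile of its k nearest RNA neighbours. A
self-imputation variant finds neighbours in the ATAC LSI space instead,
and a cluster-restricted variant limits candidates to the cell's own RNA
cluster.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from .datamodel import (Clustering, CountMatrix, Embedding, NeighborIndex,
                        PairedMultiomeDataset)
from .errors import ParameterError, StateError, ValidationError

logger = logging.getLogger(__name__)

# neighbour means of sparse rows stay mostly zero at realistic densities;
# values below this are dropped to keep the imputed matrix sparse
TRUNCATION_EPS = 1e-12


def knn_search(emb: Embedding, k: int = 50, include_self: bool = False,
               block_size: int = 1024) -> NeighborIndex:
    """Exact Euclidean k-nearest neighbours with deterministic tie-breaks.

    Ties in distance are broken toward the smaller cell index. Distances
    are computed blockwise with exact squared Euclidean distances, so
    identical coordinates give exactly zero distance.
    """
    n = emb.n_cells
    limit = n if include_self else n - 1
    if not 0 < k <= limit:
        raise ParameterError(f"k={k} out of range for {n} cells "
                             f"(include_self={include_self})")
    X = emb.coords
    indices = np.empty((n, k), dtype=np.int64)
    dists = np.empty((n, k), dtype=np.float64)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        d = cdist(X[start:stop], X, metric="sqeuclidean")
        if not include_self:
            d[np.arange(stop - start), np.arange(start, stop)] = np.inf
        # stable argsort: equal distances resolve to the smaller index
        order = np.argsort(d, axis=1, kind="stable")[:, :k]
        indices[start:stop] = order
        dists[start:stop] = np.sqrt(np.take_along_axis(d, order, axis=1))
    return NeighborIndex(indices, dists, emb.cell_ids,
                         source_embedding=emb.method,
                         includes_self=include_self)


def impute_from_neighbors(atac_norm: CountMatrix,
                          nbrs: NeighborIndex) -> CountMatrix:
    """Replace each cell's profile by the mean over its neighbours.

    Every imputed entry is a uniform average of observed values, so it
    lies within [min, max] of the neighbour values, and the output density
    can only grow.
    """
    if atac_norm.state != "normalized":
        raise StateError(
            f"impute_from_neighbors expects normalized input, got {atac_norm.state!r}"
        )
    if not np.array_equal(nbrs.cell_ids, atac_norm.cell_ids):
        raise ValidationError("neighbour index covers different cells than the matrix")
    n, k = nbrs.indices.shape
    rows = np.repeat(np.arange(n), k)
    cols = nbrs.indices.ravel()
    W = sp.csr_matrix((np.full(n * k, 1.0 / k), (rows, cols)), shape=(n, n))
    X = atac_norm.values if sp.issparse(atac_norm.values) else sp.csr_matrix(atac_norm.values)
    out = (W @ X).tocsr()
    if out.nnz:
        out.data[np.abs(out.data) < TRUNCATION_EPS] = 0.0
        out.eliminate_zeros()
    return atac_norm.with_values(out, "imputed")


def rna_guided_impute(data: PairedMultiomeDataset, rna_pca: Embedding,
                      k: int = 50, include_self: bool = False) -> CountMatrix:
    """Impute normalized ATAC from neighbours found in RNA PCA space."""
    if not np.array_equal(rna_pca.cell_ids, data.cell_ids):
        raise ValidationError("RNA embedding does not match dataset cells")
    from .preprocess import normalize_total

    atac_norm = normalize_total(data.atac)
    nbrs = knn_search(rna_pca, k=k, include_self=include_self)
    return impute_from_neighbors(atac_norm, nbrs)


def self_impute(data: PairedMultiomeDataset, atac_lsi: Embedding,
                k: int = 50, include_self: bool = False) -> CountMatrix:
    """Impute ATAC from neighbours in the (unimputed) ATAC LSI space."""
    if not np.array_equal(atac_lsi.cell_ids, data.cell_ids):
        raise ValidationError("ATAC embedding does not match dataset cells")
    from .preprocess import normalize_total

    atac_norm = normalize_total(data.atac)
    nbrs = knn_search(atac_lsi, k=k, include_self=include_self)
    return impute_from_neighbors(atac_norm, nbrs)


def cluster_restricted_impute(
    data: PairedMultiomeDataset,
    rna_pca: Embedding,
    rna_clusters: Clustering,
    k: int = 50,
) -> CountMatrix:
    """RNA-guided imputation with candidates limited to the RNA cluster.

    Reference variant: neighbour search for cell i only considers cells in
    i's RNA cluster. Clusters smaller than k+1 use all available members;
    a singleton cell keeps its own row unchanged.
    """
    if not np.array_equal(rna_clusters.cell_ids, data.cell_ids):
        raise ValidationError("clustering does not match dataset cells")
    from .preprocess import normalize_total

    atac_norm = normalize_total(data.atac)
    X = atac_norm.values.tocsr()
    n = data.n_cells
    rows_out: list[np.ndarray] = []
    cols_out: list[np.ndarray] = []
    vals_out: list[np.ndarray] = []
    coords = rna_pca.coords
    for c in range(rna_clusters.n_clusters):
        members = np.flatnonzero(rna_clusters.labels == c)
        if len(members) == 1:
            logger.warning("singleton RNA cluster %d: cell left unimputed", c)
            i = members[0]
            row = X[i]
            rows_out.append(np.full(row.nnz, i))
            cols_out.append(row.indices.copy())
            vals_out.append(row.data.copy())
            continue
        kk = min(k, len(members) - 1)
        if kk < k:
            logger.warning("cluster %d has %d cells; using k=%d",
                           c, len(members), kk)
        d = cdist(coords[members], coords[members], metric="sqeuclidean")
        np.fill_diagonal(d, np.inf)
        order = np.argsort(d, axis=1, kind="stable")[:, :kk]
        nbr_global = members[order]  # local -> global indices
        for local_i, i in enumerate(members):
            mean_row = X[nbr_global[local_i]].mean(axis=0)
            mean_row = np.asarray(mean_row).ravel()
            nz = np.flatnonzero(np.abs(mean_row) >= TRUNCATION_EPS)
            rows_out.append(np.full(len(nz), i))
            cols_out.append(nz)
            vals_out.append(mean_row[nz])
    out = sp.csr_matrix(
        (np.concatenate(vals_out), (np.concatenate(rows_out), np.concatenate(cols_out))),
        shape=(n, atac_norm.n_features),
    )
    return atac_norm.with_values(out, "imputed")
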