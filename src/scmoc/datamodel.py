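"""Core in-memory containers for paired single-cell multi-omics data.

All matrices are oriented cells x features throughout the package. The raw
on-disk 10x convention (features x cells) is handled at read time by the
I/O layer; nothing downstream ever transposes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .errors import ValidationError

MODALITIES = ("rna", "atac")
STATES = ("raw", "normalized", "log1p", "scaled", "imputed")

# States whose values must be nonnegative (scaled data is centred, so it
# is the one state allowed to go below zero).
_NONNEG_STATES = frozenset({"raw", "normalized", "log1p", "imputed"})


def _as_str_array(ids: Sequence[str]) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if arr.ndim != 1:
        raise ValidationError("identifier list must be one-dimensional")
    return arr


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate {what} identifiers")


@dataclass
class CountMatrix:
    """A cells x features matrix with identifiers and processing state.

    Parameters
    ----------
    values
        Sparse CSR (preferred for counts) or dense array, cells x features.
    cell_ids, feature_ids
        Unique, ordered identifiers matching the matrix dimensions.
    modality
        ``"rna"`` or ``"atac"``.
    state
        Processing state; one of ``raw``, ``normalized``, ``log1p``,
        ``scaled``, ``imputed``. Raw matrices hold integer counts; the
        container is reused for real-valued matrices after normalization.
    """

    values: sp.spmatrix | np.ndarray
    cell_ids: np.ndarray
    feature_ids: np.ndarray
    modality: str
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        if self.state not in STATES:
            raise ValidationError(f"unknown state {self.state!r}")
        if sp.issparse(self.values):
            self.values = self.values.tocsr()
        else:
            self.values = np.asarray(self.values, dtype=np.float64)
            if self.values.ndim != 2:
                raise ValidationError("values must be a 2-D matrix")
        self.cell_ids = _as_str_array(self.cell_ids)
        self.feature_ids = _as_str_array(self.feature_ids)
        n_cells, n_features = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(self.feature_ids) != n_features:
            raise ValidationError(
                f"{len(self.feature_ids)} feature ids for {n_features} matrix columns"
            )
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.feature_ids, "feature")
        if self.state in _NONNEG_STATES and self.min() < 0:
            raise ValidationError(
                f"negative entries not allowed in state {self.state!r}"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def min(self) -> float:
        if sp.issparse(self.values):
            return self.values.data.min() if self.values.nnz else 0.0
        return float(self.values.min()) if self.values.size else 0.0

    @property
    def nnz(self) -> int:
        if sp.issparse(self.values):
            return int(self.values.nnz)
        return int(np.count_nonzero(self.values))

    def cell_totals(self) -> np.ndarray:
        """Per-cell sum over features (library size)."""
        return np.asarray(self.values.sum(axis=1)).ravel()

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return self.values.toarray()
        return self.values

    # -- derived containers ---------------------------------------------
    def with_values(
        self, values: sp.spmatrix | np.ndarray, state: str
    ) -> "CountMatrix":
        """Same cells/features, new values and state."""
        return CountMatrix(values, self.cell_ids, self.feature_ids,
                           self.modality, state)

    def subset_cells(self, index: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.values[index], self.cell_ids[index],
                           self.feature_ids, self.modality, self.state)

    def subset_features(self, index: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.values[:, index], self.cell_ids,
                           self.feature_ids[index], self.modality, self.state)

    def cell_index(self) -> Mapping[str, int]:
        return {c: i for i, c in enumerate(self.cell_ids)}


@dataclass
class PairedMultiomeDataset:
    """RNA and ATAC matrices over one identical ordered cell set."""

    rna: CountMatrix
    atac: CountMatrix

    def __post_init__(self) -> None:
        if self.rna.modality != "rna" or self.atac.modality != "atac":
            raise ValidationError("modality tags must be rna/atac")
        if self.rna.n_cells != self.atac.n_cells or not np.array_equal(
            self.rna.cell_ids, self.atac.cell_ids
        ):
            raise ValidationError("RNA and ATAC cell ids differ")

    @property
    def cell_ids(self) -> np.ndarray:
        return self.rna.cell_ids

    @property
    def n_cells(self) -> int:
        return self.rna.n_cells

    def subset_cells(self, index: np.ndarray) -> "PairedMultiomeDataset":
        return PairedMultiomeDataset(self.rna.subset_cells(index),
                                     self.atac.subset_cells(index))


@dataclass
class Embedding:
    """Low-dimensional cell coordinates with the fit that produced them."""

    coords: np.ndarray
    method: str  # "pca" | "lsi"
    cell_ids: np.ndarray
    fit_params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2:
            raise ValidationError("embedding coordinates must be 2-D")
        self.cell_ids = _as_str_array(self.cell_ids)
        if len(self.cell_ids) != self.coords.shape[0]:
            raise ValidationError("cell ids do not match coordinate rows")
        if self.method not in ("pca", "lsi"):
            raise ValidationError(f"unknown embedding method {self.method!r}")

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


@dataclass
class Clustering:
    """Per-cell integer labels with provenance.

    Labels are consecutive integers starting at 0. Intermediate objects
    produced while splitting clusters may carry ``-1`` for temporarily
    unassigned cells when constructed with ``allow_unassigned=True``; the
    public pipeline never returns such an object.
    """

    labels: np.ndarray
    cell_ids: np.ndarray
    source: str  # rna | atac_raw | atac_imputed | scmoc
    params: dict[str, Any] = field(default_factory=dict)
    allow_unassigned: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.cell_ids = _as_str_array(self.cell_ids)
        if self.labels.ndim != 1 or len(self.labels) != len(self.cell_ids):
            raise ValidationError("labels and cell ids must align")
        assigned = self.labels[self.labels >= 0]
        if not self.allow_unassigned and len(assigned) != len(self.labels):
            raise ValidationError("negative labels not allowed")
        if len(assigned):
            uniq = np.unique(assigned)
            if uniq[0] != 0 or uniq[-1] != len(uniq) - 1:
                raise ValidationError(
                    "labels must be consecutive integers starting at 0"
                )

    @property
    def n_clusters(self) -> int:
        assigned = self.labels[self.labels >= 0]
        return int(assigned.max()) + 1 if len(assigned) else 0

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels[self.labels >= 0],
                           minlength=self.n_clusters)


def relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Map labels to 0..K-1 ordered by decreasing cluster size.

    Ties are broken by the smaller original label, so the result is a
    deterministic function of the input vector.
    """
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    order = np.lexsort((uniq, -counts))  # size desc, then original label asc
    mapping = {int(old): new for new, old in enumerate(uniq[order])}
    return np.array([mapping[int(l)] for l in labels], dtype=np.int64)


@dataclass
class NeighborIndex:
    """Exact k-nearest-neighbour lists in some embedding space."""

    indices: np.ndarray  # n_cells x k, integer cell indices
    distances: np.ndarray  # n_cells x k, nondecreasing per row
    cell_ids: np.ndarray
    source_embedding: str  # "pca" | "lsi"
    includes_self: bool = False

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.distances = np.asarray(self.distances, dtype=np.float64)
        self.cell_ids = _as_str_array(self.cell_ids)
        if self.indices.shape != self.distances.shape or self.indices.ndim != 2:
            raise ValidationError("indices/distances must be matching 2-D arrays")
        if np.any(np.diff(self.distances, axis=1) < 0):
            raise ValidationError("neighbour distances must be nondecreasing")
        if not self.includes_self:
            own = np.arange(self.indices.shape[0])[:, None]
            if np.any(self.indices == own):
                raise ValidationError("self in neighbour list with includes_self=False")

    @property
    def k(self) -> int:
        return self.indices.shape[1]


@dataclass
class ContingencyTable:
    """RNA-cluster x ATAC-cluster joint counts; drives the split rule."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or np.any(self.counts < 0):
            raise ValidationError("contingency counts must be a nonnegative 2-D array")

    @property
    def row_fractions(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, self.counts / totals, 0.0)
        return frac
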