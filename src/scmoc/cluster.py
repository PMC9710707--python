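"""Unimodal Louvain clustering and the RNA/ATAC cluster merge.

Each modality is clustered on a symmetrized kNN graph (k=50, Euclidean)
with Louvain modularity optimization at resolution 0.8. The merge trusts
the RNA clustering and only splits an RNA cluster when it overlaps more
than one ATAC cluster, each covering strictly between 10% and 90% of the
RNA cluster's cells. Cells of the RNA cluster falling in non-qualifying
ATAC clusters are then reassigned to the nearest new sub-cluster by mean
Euclidean distance in RNA PCA space.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import igraph as ig
import numpy as np

from .datamodel import (Clustering, ContingencyTable, Embedding,
                        relabel_by_size)
from .errors import ParameterError, ValidationError
from .impute import knn_search

logger = logging.getLogger(__name__)


def build_knn_graph(emb: Embedding, k: int = 50,
                    shared_neighbor_weights: bool = False) -> ig.Graph:
    """Symmetrized-union kNN graph: edge (i,j) iff j in kNN(i) or i in kNN(j).

    Unweighted by default; ``shared_neighbor_weights`` optionally weights
    each edge by the Jaccard overlap of the two endpoint neighbourhoods
    (Seurat-style SNN), off by default.
    """
    nbrs = knn_search(emb, k=k, include_self=False)
    n = emb.n_cells
    a = np.repeat(np.arange(n), k)
    b = nbrs.indices.ravel()
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    edges = np.unique(np.stack([lo, hi], axis=1), axis=0)
    g = ig.Graph(n=n, edges=[tuple(e) for e in edges], directed=False)
    if shared_neighbor_weights:
        sets = [set(row) | {i} for i, row in enumerate(nbrs.indices)]
        weights = [
            len(sets[e[0]] & sets[e[1]]) / len(sets[e[0]] | sets[e[1]])
            for e in edges
        ]
        g.es["weight"] = weights
    return g


def louvain_cluster(graph: ig.Graph, resolution: float = 0.8, seed: int = 0,
                    cell_ids: np.ndarray | None = None,
                    source: str = "rna", graph_k: int | None = None,
                    algorithm: str = "louvain") -> Clustering:
    """Louvain modularity clustering, size-ordered and seeded.

    Labels are relabelled by decreasing cluster size so outputs are
    comparable across runs; the igraph RNG is seeded for reproducibility.
    ``algorithm="leiden"`` switches to the Leiden refinement (opt-in; the
    method as published uses Louvain).
    """
    if graph.vcount() == 0:
        raise ValidationError("empty graph")
    if resolution <= 0:
        raise ParameterError("resolution must be positive")
    weights = graph.es["weight"] if "weight" in graph.es.attributes() else None
    random.seed(seed)  # python-igraph draws from Python's random module
    if algorithm == "louvain":
        part = graph.community_multilevel(weights=weights,
                                          resolution=resolution)
        membership = part.membership
    elif algorithm == "leiden":
        import leidenalg
        part = leidenalg.find_partition(
            graph, leidenalg.RBConfigurationVertexPartition,
            weights=weights, resolution_parameter=resolution, seed=seed)
        membership = part.membership
    else:
        raise ParameterError(f"unknown clustering algorithm {algorithm!r}")
    labels = relabel_by_size(np.asarray(membership))
    if cell_ids is None:
        cell_ids = np.array([f"cell_{i}" for i in range(graph.vcount())],
                            dtype=object)
    return Clustering(labels, cell_ids, source,
                      params={"resolution": resolution, "seed": seed,
                              "graph_k": graph_k})


def cluster_embedding(emb: Embedding, k: int = 50, resolution: float = 0.8,
                      seed: int = 0, source: str = "rna") -> Clustering:
    """Convenience composition: kNN graph then Louvain."""
    g = build_knn_graph(emb, k=k)
    return louvain_cluster(g, resolution=resolution, seed=seed,
                           cell_ids=emb.cell_ids, source=source, graph_k=k)


def contingency(rna: Clustering, atac: Clustering) -> ContingencyTable:
    """Joint counts of RNA x ATAC cluster membership."""
    if not np.array_equal(rna.cell_ids, atac.cell_ids):
        raise ValidationError("clusterings cover different cell sets")
    counts = np.zeros((rna.n_clusters, atac.n_clusters), dtype=np.int64)
    np.add.at(counts, (rna.labels, atac.labels), 1)
    return ContingencyTable(counts)


@dataclass
class SplitResult:
    """Intermediate outcome of the split rule, before reassignment."""

    labels: np.ndarray  # -1 marks unassigned cells
    unassigned_ids: set
    # original RNA cluster -> new sub-cluster labels carved from it
    candidates: dict[int, list[int]] = field(default_factory=dict)
    # every cell's original RNA cluster, for candidate lookup
    original_rna: np.ndarray | None = None


def split_rna_clusters(rna: Clustering, atac: Clustering,
                       low: float = 0.10, high: float = 0.90) -> SplitResult:
    """Split RNA clusters that overlap >= 2 ATAC clusters substantially.

    For RNA cluster r, an ATAC cluster a *qualifies* when the fraction of
    r's cells in a lies strictly between ``low`` and ``high``. With two or
    more qualifying ATAC clusters, r is split into one sub-cluster per
    qualifying overlap; its remaining cells become unassigned (to be
    reattached by :func:`reassign_unassigned`). With fewer than two, r is
    kept whole.
    """
    if not 0 < low < high < 1:
        raise ParameterError(f"need 0 < low < high < 1, got {low}, {high}")
    table = contingency(rna, atac)
    frac = table.row_fractions
    labels = np.full(len(rna.labels), -1, dtype=np.int64)
    unassigned: set = set()
    candidates: dict[int, list[int]] = {}
    next_label = 0
    for r in range(rna.n_clusters):
        in_r = rna.labels == r
        qualifying = np.flatnonzero((frac[r] > low) & (frac[r] < high))
        if len(qualifying) >= 2:
            subs = []
            for a in qualifying:
                sub_mask = in_r & (atac.labels == a)
                labels[sub_mask] = next_label
                subs.append(next_label)
                next_label += 1
            candidates[r] = subs
            leftover = in_r & (labels == -1)
            unassigned.update(rna.cell_ids[leftover])
        else:
            labels[in_r] = next_label
            candidates[r] = [next_label]
            next_label += 1
    return SplitResult(labels, unassigned, candidates, rna.labels.copy())


def reassign_unassigned(split: SplitResult, rna_pca: Embedding,
                        cell_ids: np.ndarray) -> np.ndarray:
    """Attach unassigned cells to the closest sub-cluster in RNA space.

    Each unassigned cell joins the candidate sub-cluster (carved from its
    own original RNA cluster) minimizing the mean Euclidean distance to the
    sub-cluster's members. Memberships are the pre-reassignment ones, so
    the result does not depend on processing order; distance ties go to
    the smaller sub-cluster label.
    """
    labels = split.labels.copy()
    if not split.unassigned_ids:
        return labels
    id_to_pos = {c: i for i, c in enumerate(cell_ids)}
    # member lists frozen before any reassignment
    members = {lab: np.flatnonzero(split.labels == lab)
               for labs in split.candidates.values() for lab in labs}
    for cid in sorted(split.unassigned_ids):
        i = id_to_pos[cid]
        cands = split.candidates[int(split.original_rna[i])]
        if not cands:
            raise ValidationError(f"cell {cid} has no candidate sub-clusters")
        best_lab, best_d = None, np.inf
        for lab in sorted(cands):
            idx = members[lab]
            d = np.linalg.norm(rna_pca.coords[idx] - rna_pca.coords[i],
                               axis=1).mean()
            if d < best_d:  # strict: ties keep the smaller label
                best_lab, best_d = lab, d
        labels[i] = best_lab
    return labels


def scmoc_merge(rna: Clustering, atac: Clustering, rna_pca: Embedding,
                low: float = 0.10, high: float = 0.90) -> Clustering:
    """The scMoC merge: split RNA clusters on ATAC evidence, reassign, relabel.

    The output refines the RNA clustering: every merged cluster lies
    entirely within one original RNA cluster.
    """
    if not np.array_equal(rna.cell_ids, atac.cell_ids) or not np.array_equal(
            rna.cell_ids, rna_pca.cell_ids):
        raise ValidationError("inputs cover different cell sets")
    split = split_rna_clusters(rna, atac, low=low, high=high)
    labels = reassign_unassigned(split, rna_pca, rna.cell_ids)
    if np.any(labels < 0):
        raise ValidationError("unassigned cells remain after reassignment")
    labels = relabel_by_size(labels)
    params = {"low": low, "high": high,
              "rna_params": rna.params, "atac_params": atac.params}
    return Clustering(labels, rna.cell_ids, "scmoc", params=params)
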