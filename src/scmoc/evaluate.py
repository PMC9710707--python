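"""Evaluation machinery: density accounting, binomial downsampling,
silhouette / ARI / neighbourhood-Jaccard / RMSE metrics, and the
downsampling and k-sensitivity sweeps used to probe when RNA-guided
imputation helps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score, silhouette_score as _sk_silhouette

from .cluster import cluster_embedding
from .datamodel import Clustering, CountMatrix, Embedding, PairedMultiomeDataset
from .errors import ParameterError, StateError, ValidationError
from .impute import impute_from_neighbors, knn_search
from .preprocess import drop_empty_cells, lsi_embed, normalize_total

logger = logging.getLogger(__name__)


@dataclass
class MetricCurve:
    """A metric traced over downsampling fractions (or k values)."""

    x: list
    y: list
    metric: str  # silhouette | ari | jaccard | rmse
    condition: str  # imputed | unimputed
    seed: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y):
            raise ValidationError("curve x and y lengths differ")


def density(m: CountMatrix) -> float:
    """Fraction of nonzero entries; sparsity is 1 - density."""
    n = m.n_cells * m.n_features
    if n == 0:
        raise ValidationError("empty matrix has no density")
    return m.nnz / n


def downsample_counts(m: CountMatrix, fraction: float, seed: int) -> CountMatrix:
    """Binomial thinning: each count unit kept independently w.p. fraction."""
    if m.state != "raw":
        raise StateError(f"downsampling expects raw counts, got {m.state!r}")
    if not 0 < fraction <= 1:
        raise ParameterError(f"fraction must be in (0, 1], got {fraction}")
    X = m.values.tocsr() if sp.issparse(m.values) else sp.csr_matrix(m.values)
    counts = X.data
    if np.any(counts != np.round(counts)):
        raise StateError("downsampling requires integer counts")
    if fraction == 1.0:
        return m.with_values(X.copy(), "raw")
    rng = np.random.default_rng(seed)
    out = X.copy()
    out.data = rng.binomial(counts.astype(np.int64), fraction).astype(X.dtype)
    out.eliminate_zeros()
    return m.with_values(out, "raw")


def silhouette(emb: Embedding, labels: Clustering) -> float:
    """Mean silhouette in the embedding's Euclidean space.

    Singleton clusters contribute 0 per the usual convention (handled by
    scikit-learn); a single-cluster labelling is undefined and errors.
    """
    if not np.array_equal(emb.cell_ids, labels.cell_ids):
        raise ValidationError("embedding and labels cover different cells")
    if labels.n_clusters < 2:
        raise ValidationError("silhouette undefined for a single cluster")
    return float(_sk_silhouette(emb.coords, labels.labels, metric="euclidean"))


def ari(a: Clustering, b: Clustering) -> float:
    """Adjusted Rand index between two clusterings of the same cells."""
    if not np.array_equal(a.cell_ids, b.cell_ids):
        raise ValidationError("clusterings cover different cell sets")
    return float(adjusted_rand_score(a.labels, b.labels))


def neighborhood_jaccard(emb_ref: Embedding, emb_test: Embedding,
                         k: int = 50) -> float:
    """Mean per-cell Jaccard overlap of k-NN sets under two embeddings."""
    if not np.array_equal(emb_ref.cell_ids, emb_test.cell_ids):
        raise ValidationError("embeddings cover different cells")
    nn_ref = knn_search(emb_ref, k=k, include_self=False)
    nn_test = knn_search(emb_test, k=k, include_self=False)
    vals = np.empty(emb_ref.n_cells)
    for i in range(emb_ref.n_cells):
        a, b = set(nn_ref.indices[i]), set(nn_test.indices[i])
        vals[i] = len(a & b) / len(a | b)
    return float(vals.mean())


def rmse(imputed: CountMatrix, reference: CountMatrix) -> float:
    """Root mean squared difference over all entries, zeros included."""
    if imputed.shape != reference.shape:
        raise ValidationError(f"shape mismatch {imputed.shape} vs {reference.shape}")
    a = imputed.values if sp.issparse(imputed.values) else sp.csr_matrix(imputed.values)
    b = reference.values if sp.issparse(reference.values) else sp.csr_matrix(reference.values)
    diff = (a - b).tocsr()
    n = imputed.n_cells * imputed.n_features
    return float(np.sqrt((diff.data ** 2).sum() / n))


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.05, 1.0001, 0.05), 2))


@dataclass
class _AtacBranch:
    """One arm of the downsampling comparison (imputed or unimputed)."""

    embedding: Embedding
    clusters: Clustering
    dens: float
    cell_mask: np.ndarray  # surviving cells relative to the full cell set


def _run_atac_branch(atac_raw: CountMatrix, rna_pca: Embedding | None,
                     impute_k: int, lsi_n: int, graph_k: int,
                     resolution: float, seed: int) -> _AtacBranch:
    """Normalize (impute) renormalize -> LSI -> Louvain on one ATAC matrix.

    ``rna_pca`` None means the unimputed branch. Cells emptied by
    downsampling are dropped first; the returned mask maps survivors back
    to the full cell set.
    """
    totals = atac_raw.cell_totals()
    mask = totals > 0
    if not mask.all():
        logger.warning("branch drops %d zero-total cells", int((~mask).sum()))
    m = atac_raw.subset_cells(np.flatnonzero(mask))
    norm = normalize_total(m)
    if rna_pca is not None:
        sub_pca = Embedding(rna_pca.coords[mask], rna_pca.method,
                            rna_pca.cell_ids[mask], rna_pca.fit_params)
        nbrs = knn_search(sub_pca, k=min(impute_k, m.n_cells - 1))
        imputed = impute_from_neighbors(norm, nbrs)
        renorm = normalize_total(imputed)
        dens = density(imputed)
        source = "atac_imputed"
    else:
        renorm = norm
        dens = density(m)
        source = "atac_raw"
    emb = lsi_embed(renorm, n_components=min(lsi_n, min(renorm.shape) - 1),
                    seed=seed)
    clusters = cluster_embedding(emb, k=min(graph_k, m.n_cells - 1),
                                 resolution=resolution, seed=seed,
                                 source=source)
    return _AtacBranch(emb, clusters, dens, mask)


def _ari_on_shared(a: Clustering, mask_a: np.ndarray,
                   b: Clustering, mask_b: np.ndarray) -> float:
    """ARI restricted to cells surviving in both branches."""
    shared = mask_a & mask_b
    pos_a = np.cumsum(mask_a) - 1
    pos_b = np.cumsum(mask_b) - 1
    la = a.labels[pos_a[shared]]
    lb = b.labels[pos_b[shared]]
    return float(adjusted_rand_score(la, lb))


def _jaccard_on_shared(ref: Embedding, mask_ref: np.ndarray,
                       test: Embedding, mask_test: np.ndarray,
                       k: int) -> float:
    shared = mask_ref & mask_test
    pos_r = np.cumsum(mask_ref) - 1
    pos_t = np.cumsum(mask_test) - 1
    er = Embedding(ref.coords[pos_r[shared]], ref.method,
                   ref.cell_ids[pos_r[shared]])
    et = Embedding(test.coords[pos_t[shared]], test.method,
                   test.cell_ids[pos_t[shared]])
    return neighborhood_jaccard(er, et, k=min(k, er.n_cells - 1))


def downsampling_experiment(
    data: PairedMultiomeDataset,
    rna_pca: Embedding,
    rna_clusters: Clustering,
    fractions: tuple = DEFAULT_FRACTIONS,
    seed: int = 0,
    impute_k: int = 50,
    lsi_n: int = 20,
    graph_k: int = 50,
    resolution: float = 0.8,
    jaccard_k: int = 50,
) -> list[MetricCurve]:
    """Downsample ATAC counts and compare imputed vs unimputed branches.

    For each fraction, the raw ATAC counts are binomially thinned and both
    branches (RNA-guided imputed and unimputed) are run through
    normalization, LSI and Louvain. Recorded per fraction and branch:
    silhouette of the branch's clusters in its own LSI space, ARI against
    the full-data RNA clusters, ARI against full-data unimputed and
    imputed ATAC clusters, and mean 50-NN Jaccard against the branch's
    full-data embedding.
    """
    fractions = tuple(sorted(fractions))
    if not all(0 < f <= 1 for f in fractions):
        raise ParameterError("fractions must lie in (0, 1]")
    full_mask = np.ones(data.n_cells, dtype=bool)
    branch_args = dict(impute_k=impute_k, lsi_n=lsi_n, graph_k=graph_k,
                       resolution=resolution, seed=seed)
    full_unimp = _run_atac_branch(data.atac, None, **branch_args)
    full_imp = _run_atac_branch(data.atac, rna_pca, **branch_args)

    results: dict[tuple[str, str], list[float]] = {}
    densities: dict[str, list[float]] = {"imputed": [], "unimputed": []}
    for fi, frac in enumerate(fractions):
        ds = downsample_counts(data.atac, frac, seed=seed + 1000 + fi)
        for cond, guide, full_branch in (
            ("unimputed", None, full_unimp),
            ("imputed", rna_pca, full_imp),
        ):
            br = _run_atac_branch(ds, guide, **branch_args)
            densities[cond].append(br.dens)
            sil = (silhouette(br.embedding, br.clusters)
                   if br.clusters.n_clusters >= 2 else 0.0)
            results.setdefault(("silhouette", cond), []).append(sil)
            results.setdefault(("ari_vs_rna", cond), []).append(
                _ari_on_shared(br.clusters, br.cell_mask, rna_clusters, full_mask))
            results.setdefault(("ari_vs_full_unimputed", cond), []).append(
                _ari_on_shared(br.clusters, br.cell_mask,
                               full_unimp.clusters, full_unimp.cell_mask))
            results.setdefault(("ari_vs_full_imputed", cond), []).append(
                _ari_on_shared(br.clusters, br.cell_mask,
                               full_imp.clusters, full_imp.cell_mask))
            results.setdefault(("jaccard", cond), []).append(
                _jaccard_on_shared(full_branch.embedding, full_branch.cell_mask,
                                   br.embedding, br.cell_mask, jaccard_k))
    curves = [
        MetricCurve(list(fractions), vals, metric, cond, seed,
                    meta={"densities": densities[cond],
                          "silhouette_space": "branch LSI"})
        for (metric, cond), vals in results.items()
    ]
    return curves


def k_sensitivity(
    data: PairedMultiomeDataset,
    rna_pca: Embedding,
    rna_clusters: Clustering,
    ks: tuple = tuple(range(10, 101, 10)),
    seed: int = 0,
    lsi_n: int = 20,
    graph_k: int = 50,
    resolution: float = 0.8,
    low: float = 0.10,
    high: float = 0.90,
) -> MetricCurve:
    """Silhouette of the merged clusters as the imputation k varies.

    All other parameters stay at their defaults; silhouette is measured in
    the imputed-ATAC LSI space of each run.
    """
    from .cluster import scmoc_merge

    if max(ks) >= data.n_cells:
        raise ParameterError("largest k must be below the number of cells")
    sils = []
    for k in ks:
        branch = _run_atac_branch(data.atac, rna_pca, impute_k=k,
                                  lsi_n=lsi_n, graph_k=graph_k,
                                  resolution=resolution, seed=seed)
        merged = scmoc_merge(rna_clusters, branch.clusters, rna_pca,
                             low=low, high=high)
        sil = (silhouette(branch.embedding,
                          Clustering(merged.labels, merged.cell_ids,
                                     "scmoc", merged.params))
               if merged.n_clusters >= 2 else 0.0)
        sils.append(sil)
    return MetricCurve(list(ks), sils, "silhouette", "imputed", seed,
                       meta={"swept": "impute_k",
                             "silhouette_space": "imputed LSI"})
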