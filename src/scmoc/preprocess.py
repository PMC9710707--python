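"""Quality control, normalization and dimensionality reduction.

The RNA branch follows the standard single-cell recipe: total-count
normalization to 1e4 per cell, log1p, selection of highly variable genes
by the variance-stabilizing-transform (vst) ranking on raw counts,
per-gene z-scaling with clipping, and PCA to 20 components.

The ATAC branch is embedded with latent semantic indexing (LSI):
log-TF-IDF weighting followed by a truncated SVD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .datamodel import CountMatrix, Embedding, PairedMultiomeDataset
from .errors import ParameterError, QCError, StateError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    """Per-modality cell and feature filters.

    All thresholds are inclusive bounds on what is *kept*.
    """

    min_counts_per_cell: float = 0.0
    max_counts_per_cell: float = np.inf
    min_features_per_cell: int = 0
    min_cells_per_feature: int = 0

    def __post_init__(self) -> None:
        if self.min_counts_per_cell > self.max_counts_per_cell:
            raise ParameterError("min_counts_per_cell exceeds max_counts_per_cell")
        if min(self.min_counts_per_cell, self.min_features_per_cell,
               self.min_cells_per_feature) < 0:
            raise ParameterError("QC thresholds must be nonnegative")

    def cell_mask(self, m: CountMatrix) -> np.ndarray:
        totals = m.cell_totals()
        n_feats = np.asarray((m.values > 0).sum(axis=1)).ravel()
        return (
            (totals >= self.min_counts_per_cell)
            & (totals <= self.max_counts_per_cell)
            & (n_feats >= self.min_features_per_cell)
        )


@dataclass
class HVGResult:
    """Outcome of vst highly-variable-gene selection."""

    selected_feature_ids: np.ndarray
    standardized_variance: np.ndarray  # per input feature
    fitted_trend: np.ndarray  # expected variance per input feature
    feature_ids: np.ndarray = field(default=None)  # all input features


def qc_filter(
    data: PairedMultiomeDataset,
    rna_thresholds: QCThresholds,
    atac_thresholds: QCThresholds,
) -> PairedMultiomeDataset:
    """Drop cells failing either modality's thresholds, then sparse features.

    A cell is kept only if it passes BOTH modalities' cell filters, so the
    paired invariant (one shared cell set) is preserved. Feature filters
    (``min_cells_per_feature``) are applied per modality after cell
    filtering.
    """
    keep = rna_thresholds.cell_mask(data.rna) & atac_thresholds.cell_mask(data.atac)
    if not keep.any():
        raise QCError(
            "QC removed every cell "
            f"(RNA pass: {int(rna_thresholds.cell_mask(data.rna).sum())}, "
            f"ATAC pass: {int(atac_thresholds.cell_mask(data.atac).sum())})"
        )
    logger.info("QC kept %d/%d cells", int(keep.sum()), len(keep))
    out = data.subset_cells(np.flatnonzero(keep))
    rna, atac = out.rna, out.atac
    for thr, m, name in ((rna_thresholds, rna, "rna"), (atac_thresholds, atac, "atac")):
        if thr.min_cells_per_feature > 0:
            n_cells = np.asarray((m.values > 0).sum(axis=0)).ravel()
            fkeep = n_cells >= thr.min_cells_per_feature
            logger.info("QC kept %d/%d %s features", int(fkeep.sum()), len(fkeep), name)
            if name == "rna":
                rna = m.subset_features(np.flatnonzero(fkeep))
            else:
                atac = m.subset_features(np.flatnonzero(fkeep))
    return PairedMultiomeDataset(rna, atac)


def drop_empty_cells(data: PairedMultiomeDataset) -> PairedMultiomeDataset:
    """Remove cells with a zero total in either modality (with a warning).

    Used after aggressive downsampling, which can empty out cells that
    passed the original QC.
    """
    keep = (data.rna.cell_totals() > 0) & (data.atac.cell_totals() > 0)
    if not keep.all():
        logger.warning("dropping %d zero-total cells", int((~keep).sum()))
        return data.subset_cells(np.flatnonzero(keep))
    return data


def normalize_total(m: CountMatrix, scale_factor: float = 1e4) -> CountMatrix:
    """Divide each cell by its total count and scale to ``scale_factor``."""
    if m.state not in ("raw", "imputed"):
        raise StateError(f"normalize_total expects raw or imputed input, got {m.state!r}")
    if scale_factor <= 0:
        raise ParameterError("scale_factor must be positive")
    totals = m.cell_totals()
    zero = np.flatnonzero(totals == 0)
    if len(zero):
        raise ValidationError(
            f"cell(s) with zero total count: {list(m.cell_ids[zero[:5]])}"
        )
    if sp.issparse(m.values):
        scaled = sp.diags(scale_factor / totals) @ m.values
    else:
        scaled = m.values * (scale_factor / totals)[:, None]
    return m.with_values(scaled, "normalized")


def log1p_transform(m: CountMatrix) -> CountMatrix:
    """Natural log(1 + x); zeros stay zero so sparsity is preserved."""
    if m.state != "normalized":
        raise StateError(f"log1p expects normalized input, got {m.state!r}")
    if sp.issparse(m.values):
        out = m.values.copy()
        out.data = np.log1p(out.data)
    else:
        out = np.log1p(m.values)
    return m.with_values(out, "log1p")


# ---------------------------------------------------------------------------
# Highly variable genes (vst)
# ---------------------------------------------------------------------------

def _loess_fit(x: np.ndarray, y: np.ndarray, span: float = 0.3,
               degree: int = 2) -> np.ndarray:
    """Local polynomial regression with tricube weights.

    Fits y ~ poly(x, degree) in a sliding window containing ``span`` of the
    points, evaluated at each x. Plain O(n^2) implementation; gene counts in
    this pipeline are a few thousand.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    r = max(degree + 1, int(np.ceil(span * n)))
    r = min(r, n)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    fitted_sorted = np.empty(n)
    powers = np.arange(degree + 1)
    lo = 0
    for i in range(n):
        # slide the window of r points to be as centred on xs[i] as possible
        while lo + r < n and xs[lo + r] - xs[i] < xs[i] - xs[lo]:
            lo += 1
        window = slice(lo, lo + r)
        xw, yw = xs[window], ys[window]
        d = np.abs(xw - xs[i])
        dmax = d.max()
        if dmax == 0:
            fitted_sorted[i] = yw.mean()
            continue
        w = (1 - (d / dmax) ** 3) ** 3
        w = np.clip(w, 0, None)
        X = (xw[:, None] - xs[i]) ** powers  # centred design, intercept = fit
        WX = X * w[:, None]
        beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ yw, rcond=None)
        fitted_sorted[i] = beta[0]
    fitted = np.empty(n)
    fitted[order] = fitted_sorted
    return fitted


def select_hvg_vst(m_raw: CountMatrix, n_hvg: int = 6000,
                   span: float = 0.3) -> HVGResult:
    """Rank genes by variance of clipped standardized raw counts.

    Implements the vst ranking: per-gene mean and variance of raw counts;
    a loess fit of log10(variance) on log10(mean) (degree 2, span 0.3) over
    genes with positive variance gives each gene an expected standard
    deviation; counts are standardized by (x - mean)/expected_sd, clipped
    at sqrt(n_cells), and the variance of the clipped values ranks genes.
    """
    if m_raw.state != "raw":
        raise StateError(f"vst operates on raw counts, got state {m_raw.state!r}")
    if n_hvg > m_raw.n_features:
        raise ParameterError(
            f"n_hvg={n_hvg} exceeds {m_raw.n_features} features"
        )
    n = m_raw.n_cells
    if n < 2:
        raise ParameterError("need at least 2 cells for variance estimation")
    X = m_raw.values
    mean = np.asarray(X.mean(axis=0)).ravel()
    if sp.issparse(X):
        sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    else:
        sq = (X ** 2).mean(axis=0)
    var = (sq - mean ** 2) * n / (n - 1)
    var = np.clip(var, 0, None)

    positive = var > 0
    fitted_trend = np.zeros_like(var)
    std_var = np.zeros_like(var)
    if positive.any():
        logm = np.log10(mean[positive])
        logv = np.log10(var[positive])
        fitted_trend[positive] = 10 ** _loess_fit(logm, logv, span=span)
        exp_sd = np.sqrt(fitted_trend[positive])
        clip = np.sqrt(n)
        # variance of clipped standardized values, computed sparsely:
        # all zero entries of a gene share the value (0 - mu)/sd.
        cols = np.flatnonzero(positive)
        Xc = X.tocsc() if sp.issparse(X) else X
        for out_i, (j, mu, sd) in enumerate(zip(cols, mean[positive], exp_sd)):
            if sp.issparse(Xc):
                data = Xc.data[Xc.indptr[j]:Xc.indptr[j + 1]]
            else:
                data = Xc[:, j][Xc[:, j] != 0]
            z_nz = np.clip((data - mu) / sd, -clip, clip)
            z_zero = np.clip(-mu / sd, -clip, clip)
            n_zero = n - len(data)
            s1 = z_nz.sum() + n_zero * z_zero
            s2 = (z_nz ** 2).sum() + n_zero * z_zero ** 2
            std_var[j] = (s2 - s1 ** 2 / n) / (n - 1)
    else:
        logger.warning("all features have zero variance; "
                       "selecting the first %d by feature order", n_hvg)
        return HVGResult(m_raw.feature_ids[:n_hvg].copy(), std_var,
                         fitted_trend, m_raw.feature_ids)

    # rank by standardized variance desc; ties broken by feature id asc
    order = np.lexsort((m_raw.feature_ids.astype(str), -std_var))
    selected = m_raw.feature_ids[order[:n_hvg]]
    return HVGResult(selected, std_var, fitted_trend, m_raw.feature_ids)


def subset_to_features(m: CountMatrix, feature_ids: np.ndarray) -> CountMatrix:
    """Subset columns to ``feature_ids`` in the given order."""
    index = {f: i for i, f in enumerate(m.feature_ids)}
    try:
        cols = np.array([index[f] for f in feature_ids])
    except KeyError as exc:
        raise ValidationError(f"feature {exc.args[0]!r} not in matrix")
    return m.subset_features(cols)


def scale_features(m: CountMatrix, clip: float = 10.0) -> CountMatrix:
    """Per-feature z-score (population sd) with clipping to [-clip, clip]."""
    if m.state != "log1p":
        raise StateError(f"scale_features expects log1p input, got {m.state!r}")
    if clip <= 0:
        raise ParameterError("clip must be positive")
    X = m.dense()
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # ddof=0
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd_safe
    Z[:, sd == 0] = 0.0
    np.clip(Z, -clip, clip, out=Z)
    return m.with_values(Z, "scaled")


# ---------------------------------------------------------------------------
# Embeddings
# ---------------------------------------------------------------------------

def _fix_signs(coords: np.ndarray, components: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each component so its largest-magnitude loading is positive."""
    for j in range(components.shape[0]):
        i = np.argmax(np.abs(components[j]))
        if components[j, i] < 0:
            components[j] *= -1
            coords[:, j] *= -1
    return coords, components


def pca_embed(m: CountMatrix, n_components: int = 20, seed: int = 0) -> Embedding:
    """PCA on scaled data; components ordered by explained variance."""
    if m.state != "scaled":
        raise StateError(f"pca_embed expects scaled input, got {m.state!r}")
    if not 0 < n_components < min(m.n_cells, m.n_features):
        raise ParameterError(
            f"n_components={n_components} out of range for shape {m.shape}"
        )
    X = m.dense()
    solver = "full" if min(X.shape) <= 1000 else "randomized"
    p = PCA(n_components=n_components, svd_solver=solver, random_state=seed)
    coords = p.fit_transform(X)
    components = p.components_.copy()
    coords, components = _fix_signs(coords, components)
    return Embedding(
        coords, "pca", m.cell_ids,
        fit_params={
            "components": components,
            "mean": p.mean_,
            "explained_variance_ratio": p.explained_variance_ratio_,
            "n_components": n_components,
            "seed": seed,
        },
    )


def tfidf_transform(m: CountMatrix, scale_factor: float = 1e4) -> sp.csr_matrix:
    """log(1 + TF * IDF * scale) weighting of a nonnegative matrix.

    TF is the within-cell term frequency (row-normalized values) and
    IDF[j] = n_cells / (1 + number of cells with feature j nonzero).
    """
    X = m.values.tocsr() if sp.issparse(m.values) else sp.csr_matrix(m.values)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValidationError("all-zero cell in LSI input")
    df = np.asarray((X > 0).sum(axis=0)).ravel()
    idf = X.shape[0] / (1.0 + df)
    out = sp.diags(1.0 / totals) @ X @ sp.diags(idf)
    out = out.tocsr()
    out.data = np.log1p(out.data * scale_factor)
    return out


def lsi_embed(m: CountMatrix, n_components: int = 20, seed: int = 0,
              drop_first: bool = False) -> Embedding:
    """Latent semantic indexing: log-TF-IDF followed by truncated SVD.

    ``drop_first`` removes the leading component (often correlated with
    sequencing depth in chromatin data); the default keeps all components.
    """
    if m.state not in ("normalized", "imputed", "raw"):
        raise StateError(f"lsi_embed expects nonnegative counts, got {m.state!r}")
    n_fit = n_components + (1 if drop_first else 0)
    if not 0 < n_fit < min(m.n_cells, m.n_features):
        raise ParameterError(
            f"n_components={n_components} out of range for shape {m.shape}"
        )
    T = tfidf_transform(m)
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(min(T.shape))
    u, s, vt = sp.linalg.svds(T, k=n_fit, v0=v0)
    order = np.argsort(-s)  # svds returns ascending
    u, s, vt = u[:, order], s[order], vt[order]
    coords = u * s
    coords, components = _fix_signs(coords, vt)
    if drop_first:
        coords, components, s = coords[:, 1:], components[1:], s[1:]
    return Embedding(
        coords, "lsi", m.cell_ids,
        fit_params={
            "components": components,
            "singular_values": s,
            "n_components": n_components,
            "drop_first": drop_first,
            "seed": seed,
        },
    )


def rna_branch(
    rna_raw: CountMatrix,
    n_hvg: int = 6000,
    n_components: int = 20,
    scale_clip: float = 10.0,
    seed: int = 0,
) -> Embedding:
    """Full RNA preprocessing: normalize, log1p, HVG, scale, PCA."""
    n_hvg = min(n_hvg, rna_raw.n_features)
    hvg = select_hvg_vst(rna_raw, n_hvg=n_hvg)
    norm = normalize_total(rna_raw)
    logn = log1p_transform(norm)
    sub = subset_to_features(logn, hvg.selected_feature_ids)
    scaled = scale_features(sub, clip=scale_clip)
    return pca_embed(scaled, n_components=n_components, seed=seed)
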