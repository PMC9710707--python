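"""End-to-end orchestration of the scMoC pipeline.

The library entry point is :func:`run_scmoc`, which takes an in-memory
paired dataset and returns every intermediate the method produces
(embeddings, per-modality clusterings, the imputed matrix, the merged
clustering and summary metrics). :func:`run_pipeline` wraps it with file
I/O for the command line.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import io as scio
from .cluster import cluster_embedding, scmoc_merge
from .datamodel import Clustering, CountMatrix, Embedding, PairedMultiomeDataset
from .errors import ConfigError
from .impute import cluster_restricted_impute, rna_guided_impute, self_impute
from .preprocess import (QCThresholds, lsi_embed, normalize_total, qc_filter,
                         rna_branch)

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Every tunable of the pipeline, with the method's defaults."""

    qc_rna: QCThresholds = field(default_factory=QCThresholds)
    qc_atac: QCThresholds = field(default_factory=QCThresholds)
    hvg_n: int = 6000
    pca_n: int = 20
    lsi_n: int = 20
    scale_clip: float = 10.0
    impute_k: int = 50
    impute_method: str = "rna_guided"  # rna_guided | self | cluster_restricted
    include_self: bool = False
    cluster_k: int = 50
    resolution: float = 0.8
    merge_low: float = 0.10
    merge_high: float = 0.90
    seed: int = 0

    def stage_seeds(self) -> dict[str, int]:
        """Independent per-stage seeds derived from the root seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ("pca", "lsi", "louvain_rna", "louvain_atac", "misc")
        children = ss.spawn(len(names))
        return {name: int(child.generate_state(1)[0] % (2 ** 31))
                for name, child in zip(names, children)}


# nested YAML schema -> PipelineParams field (+ type)
_CONFIG_SCHEMA = {
    ("qc", "rna", "min_counts"): ("qc_rna", "min_counts_per_cell", float),
    ("qc", "rna", "max_counts"): ("qc_rna", "max_counts_per_cell", float),
    ("qc", "rna", "min_features"): ("qc_rna", "min_features_per_cell", int),
    ("qc", "rna", "min_cells_per_feature"): ("qc_rna", "min_cells_per_feature", int),
    ("qc", "atac", "min_counts"): ("qc_atac", "min_counts_per_cell", float),
    ("qc", "atac", "max_counts"): ("qc_atac", "max_counts_per_cell", float),
    ("qc", "atac", "min_features"): ("qc_atac", "min_features_per_cell", int),
    ("qc", "atac", "min_cells_per_feature"): ("qc_atac", "min_cells_per_feature", int),
    ("hvg", "n"): ("hvg_n", None, int),
    ("pca", "n"): ("pca_n", None, int),
    ("lsi", "n"): ("lsi_n", None, int),
    ("scale", "clip"): ("scale_clip", None, float),
    ("impute", "k"): ("impute_k", None, int),
    ("impute", "method"): ("impute_method", None, str),
    ("impute", "include_self"): ("include_self", None, bool),
    ("cluster", "k"): ("cluster_k", None, int),
    ("cluster", "resolution"): ("resolution", None, float),
    ("merge", "low"): ("merge_low", None, float),
    ("merge", "high"): ("merge_high", None, float),
    ("seed",): ("seed", None, int),
}


def _flatten(d: Any, prefix: tuple = ()) -> dict[tuple, Any]:
    out = {}
    if isinstance(d, dict):
        for k, v in d.items():
            out.update(_flatten(v, prefix + (str(k),)))
    else:
        out[prefix] = d
    return out


def load_config(path: str | Path | None = None,
                mapping: dict | None = None) -> PipelineParams:
    """Build :class:`PipelineParams` from YAML; unknown keys are rejected."""
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            mapping = yaml.safe_load(fh) or {}
    mapping = mapping or {}
    params = PipelineParams()
    for key, value in _flatten(mapping).items():
        if key not in _CONFIG_SCHEMA:
            raise ConfigError(f"unknown config key {'.'.join(key)!r}")
        attr, sub, typ = _CONFIG_SCHEMA[key]
        value = typ(value)
        if sub is None:
            setattr(params, attr, value)
        else:
            setattr(getattr(params, attr), sub, value)
    if params.impute_method not in ("rna_guided", "self", "cluster_restricted"):
        raise ConfigError(f"unknown impute method {params.impute_method!r}")
    return params


def effective_config(params: PipelineParams) -> dict:
    """The resolved configuration, for echoing next to the outputs."""
    cfg = asdict(params)
    cfg["stage_seeds"] = params.stage_seeds()
    cfg["qc_rna"]["max_counts_per_cell"] = (
        None if np.isinf(params.qc_rna.max_counts_per_cell)
        else params.qc_rna.max_counts_per_cell)
    cfg["qc_atac"]["max_counts_per_cell"] = (
        None if np.isinf(params.qc_atac.max_counts_per_cell)
        else params.qc_atac.max_counts_per_cell)
    return cfg


@dataclass
class ScmocResult:
    """Everything one pipeline run produces."""

    data: PairedMultiomeDataset  # post-QC
    rna_pca: Embedding
    atac_lsi: Embedding
    imputed: CountMatrix
    rna_clusters: Clustering
    atac_clusters: Clustering
    scmoc_clusters: Clustering
    metrics: dict


def run_scmoc(data: PairedMultiomeDataset,
              params: PipelineParams | None = None,
              apply_qc: bool = True) -> ScmocResult:
    """Run the full method: QC, RNA branch, imputation, ATAC branch, merge."""
    from .evaluate import density

    params = params or PipelineParams()
    seeds = params.stage_seeds()
    if apply_qc:
        data = qc_filter(data, params.qc_rna, params.qc_atac)

    rna_pca = rna_branch(data.rna, n_hvg=params.hvg_n,
                         n_components=params.pca_n,
                         scale_clip=params.scale_clip, seed=seeds["pca"])
    rna_clusters = cluster_embedding(rna_pca, k=params.cluster_k,
                                     resolution=params.resolution,
                                     seed=seeds["louvain_rna"], source="rna")

    if params.impute_method == "rna_guided":
        imputed = rna_guided_impute(data, rna_pca, k=params.impute_k,
                                    include_self=params.include_self)
    elif params.impute_method == "self":
        atac_norm = normalize_total(data.atac)
        pre_lsi = lsi_embed(atac_norm, n_components=params.lsi_n,
                            seed=seeds["lsi"])
        imputed = self_impute(data, pre_lsi, k=params.impute_k,
                              include_self=params.include_self)
    elif params.impute_method == "cluster_restricted":
        imputed = cluster_restricted_impute(data, rna_pca, rna_clusters,
                                            k=params.impute_k)
    else:  # pragma: no cover - guarded at config load
        raise ConfigError(f"unknown impute method {params.impute_method!r}")

    renorm = normalize_total(imputed)
    atac_lsi = lsi_embed(renorm, n_components=params.lsi_n, seed=seeds["lsi"])
    atac_clusters = cluster_embedding(atac_lsi, k=params.cluster_k,
                                      resolution=params.resolution,
                                      seed=seeds["louvain_atac"],
                                      source="atac_imputed")

    merged = scmoc_merge(rna_clusters, atac_clusters, rna_pca,
                         low=params.merge_low, high=params.merge_high)

    metrics = {
        "n_cells": int(data.n_cells),
        "density_atac_raw": density(data.atac),
        "density_atac_imputed": density(imputed),
        "density_rna_raw": density(data.rna),
        "n_rna_clusters": rna_clusters.n_clusters,
        "n_atac_clusters": atac_clusters.n_clusters,
        "n_scmoc_clusters": merged.n_clusters,
    }
    return ScmocResult(data, rna_pca, atac_lsi, imputed, rna_clusters,
                       atac_clusters, merged, metrics)


def run_pipeline(data: PairedMultiomeDataset, params: PipelineParams,
                 out_dir: str | Path, write_imputed: bool = False) -> ScmocResult:
    """Run the method and write all artifacts into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = run_scmoc(data, params)
    scio.write_labels(
        [result.rna_clusters, result.atac_clusters, result.scmoc_clusters],
        out / "labels.tsv",
        names=["rna_cluster", "atac_cluster", "scmoc_cluster"],
    )
    scio.write_embedding_csv(result.rna_pca, out / "rna_pca.csv")
    scio.write_embedding_csv(result.atac_lsi, out / "atac_lsi.csv")
    with open(out / "metrics.json", "w", encoding="utf-8") as fh:
        json.dump(result.metrics, fh, indent=2, sort_keys=True)
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(effective_config(params), fh)
    if write_imputed:
        scio.write_counts_mtx(result.imputed, out / "atac_imputed.mtx",
                              out / "imputed_barcodes.tsv",
                              out / "imputed_features.tsv")
    logger.info("pipeline finished: %s", result.metrics)
    return result
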