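"""Shared fixtures: small synthetic paired datasets and one full run.

The expensive 2000-cell scenario (four major groups, one split 40/60 into
subgroups that differ strongly in ATAC and only weakly in RNA) is built
once per session and shared by the evaluation and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from scmoc import (CountMatrix, PairedMultiomeDataset, PipelineParams,
                   SyntheticSpec, generate, run_scmoc)


def make_counts(values, modality="rna", state="raw", cell_prefix="c",
                feature_prefix="f") -> CountMatrix:
    """Small dense-specified CountMatrix for unit tests."""
    values = np.asarray(values, dtype=float)
    cells = [f"{cell_prefix}{i}" for i in range(values.shape[0])]
    feats = [f"{feature_prefix}{j}" for j in range(values.shape[1])]
    return CountMatrix(sp.csr_matrix(values), cells, feats, modality, state)


@pytest.fixture(scope="session")
def small_paired():
    """400 cells, 3 major groups, no fine substructure; fast to process."""
    spec = SyntheticSpec(n_cells=400, n_genes=600, n_peaks=1500,
                         major_groups=3, target_rna_density=0.03,
                         target_atac_density=0.01, seed=7)
    return generate(spec)


@pytest.fixture(scope="session")
def recovery_scenario():
    """The label-recovery study conditions: 2000 cells, 4 major groups,
    group 0 split 40/60 into subgroups that differ strongly in chromatin
    accessibility and weakly (fold 5 on 50/2000 genes) in expression —
    too weakly for RNA-only clustering to separate them."""
    spec = SyntheticSpec(n_cells=2000, target_rna_density=0.0706,
                         target_atac_density=0.01,
                         atac_subgroups={0: 2},
                         subgroup_proportions={0: (0.4, 0.6)},
                         rna_leak=4.0, seed=1)
    data, truth = generate(spec)
    return spec, data, truth


@pytest.fixture(scope="session")
def recovery_result(recovery_scenario):
    _, data, _ = recovery_scenario
    return run_scmoc(data, PipelineParams(seed=1))
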