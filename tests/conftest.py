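"""Shared fixtures: session-scoped simulations reused across modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import ovatlas as ov
from ovatlas.iodata import CountMatrix
from ovatlas.synthetic import LineageSpec, TypeSpec


def make_count_matrix(array, mito_flags=None, barcodes=None):
    """Small dense-array CountMatrix for unit examples."""
    arr = np.asarray(array, dtype=np.int64)
    n_cells, n_genes = arr.shape
    return CountMatrix(
        counts=sp.csr_matrix(arr),
        barcodes=barcodes or [f"BC{i}" for i in range(n_cells)],
        gene_ids=[f"G{j}" for j in range(n_genes)],
        gene_symbols=[f"g{j}" for j in range(n_genes)],
        mito_flags=(
            np.zeros(n_genes, dtype=bool) if mito_flags is None else mito_flags
        ),
    )


@pytest.fixture(scope="session")
def discrete_sim():
    """Default six-type simulation with doublets and planted QC failures."""
    design = ov.default_discrete_design(seed=0)
    cm, gt, panel = ov.simulate_atlas(design)
    return design, cm, gt, panel


@pytest.fixture(scope="session")
def small_sim():
    """Fast four-type simulation for unit-level checks."""
    design = ov.SimulationDesign(
        n_genes=800,
        n_cells=600,
        discrete_types=tuple(
            TypeSpec(name=n, n_marker_genes=25) for n in "abcd"
        ),
        doublet_rate=0.08,
        cycling_fraction=0.2,
        seed=7,
    )
    cm, gt, panel = ov.simulate_atlas(design)
    return design, cm, gt, panel


@pytest.fixture(scope="session")
def branched_sim():
    """Default branched-lineage simulation."""
    design = ov.default_branched_design(seed=0)
    cm, gt, panel = ov.simulate_atlas(design)
    return design, cm, gt, panel


@pytest.fixture(scope="session")
def filtered_discrete(discrete_sim):
    """QC-filtered default simulation with truth aligned to kept cells."""
    _, cm, gt, panel = discrete_sim
    kept, report = ov.filter_cells(cm, ov.compute_qc_metrics(cm))
    truth = gt.cells.set_index("barcode").loc[kept.barcodes].reset_index()
    return kept, truth, gt, panel


@pytest.fixture(scope="session")
def normalized_discrete(filtered_discrete):
    cm, truth, gt, panel = filtered_discrete
    return ov.lognormalize(cm), cm, truth, gt, panel
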