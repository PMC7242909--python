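import numpy as np
import pandas as pd
import pytest

import sccrosstalk as sct


@pytest.fixture(scope="session")
def sim_default():
    """Default synthetic dataset: 4 clusters x 50 cells, fold-8 markers."""
    matrix, truth = sct.simulate_matrix(sct.SimConfig(seed=0))
    return matrix, truth


@pytest.fixture(scope="session")
def sim_processed(sim_default):
    """QC'd, renormalized, log-transformed version plus true-label assignment."""
    matrix, truth = sim_default
    proc, _ = sct.run_qc(matrix, sct.QCThresholds(min_detected_genes=300))
    assign = sct.ClusterAssignment(
        pd.Series(truth.labels(proc.cells), index=proc.cells))
    return proc, truth, assign


@pytest.fixture
def toy_lr_matrix():
    """6-cell, 2-gene toy: ligand only in cluster 0, receptor only in cluster 1."""
    vals = np.array([[9.0, 9, 9, 0, 0, 0],
                     [0.0, 0, 0, 9, 9, 9]])
    m = sct.ExpressionMatrix(vals, genes=["L1", "R1"],
                             cells=[f"c{i}" for i in range(6)])
    assign = sct.ClusterAssignment(pd.Series([0, 0, 0, 1, 1, 1], index=m.cells))
    return m, assign
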