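import numpy as np
import pytest

from lineagetrace.io import SignatureList
from lineagetrace.scrna import normalize_log
from lineagetrace.simulate import SimParams, simulate_bifurcating_expression


@pytest.fixture(scope="session")
def basophil_sim():
    """Single-trajectory (trunk + branchA) fixture at the default study scale:
    300 cells, 2000 genes, 10% dynamic genes with >=1 log-unit effects."""
    params = SimParams(n_cells=300, n_genes=2000, seed=11, p_branch_a=1.0)
    return simulate_bifurcating_expression(params)


@pytest.fixture(scope="session")
def basophil_lognorm(basophil_sim):
    matrix, _ = basophil_sim
    return normalize_log(matrix)


@pytest.fixture(scope="session")
def small_sim():
    """A fast small fixture for unit-level checks."""
    params = SimParams(n_cells=120, n_genes=300, seed=3, p_branch_a=1.0, frac_cycle=0.0)
    return simulate_bifurcating_expression(params)


def truth_signature(truth, gene_class, name=None):
    genes = {g for g, c in zip(truth.gene_ids, truth.gene_class) if c == gene_class}
    return SignatureList(name or gene_class, genes)


def orientation_markers(truth, n=3):
    """Planted decreasing genes, usable as progenitor-marker stand-ins."""
    return [g for g, c in zip(truth.gene_ids, truth.gene_class) if c == "down"][:n]
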