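import numpy as np
import pandas as pd
import pytest

from matte import (
    AnalysisConfig,
    ExpressionMatrix,
    PhenotypeTable,
    SimulationSpec,
    simulate_expression,
)
from matte.simulator import combined_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_expr(rng):
    """5 genes x 8 samples of positive expression, TPM-like scale."""
    values = pd.DataFrame(
        rng.uniform(1, 100, size=(5, 8)),
        index=[f"G{i}" for i in range(5)],
        columns=[f"S{i}" for i in range(8)],
    )
    return ExpressionMatrix(values, unit="tpm")


@pytest.fixture
def two_pheno_dataset():
    """Small nine-group simulation with the matching phenotype table."""
    spec = SimulationSpec(ng_per_group=8, ns=40, seed=7)
    expr_p1, expr_p2, truth = simulate_expression(spec)
    combined, pheno_df = combined_matrix(expr_p1, expr_p2)
    pheno = PhenotypeTable.from_pairs(
        list(zip(pheno_df["sample"], pheno_df["phenotype"]))
    )
    return combined, pheno, truth, expr_p1, expr_p2


@pytest.fixture
def default_config():
    return AnalysisConfig(mode="de", n_clusters=6, seed=0)
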