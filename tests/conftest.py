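"""Shared fixtures: small synthetic cohorts and trained models.

Everything is generated programmatically with fixed seeds; session scope
keeps the pipeline runs (train once, probe many times) cheap.
"""

import numpy as np
import pandas as pd
import pytest

from gerclass.expression_io import ExpressionMatrix, LabelSet
from gerclass.ger_model import train_on_dataset
from gerclass.synth import SimConfig, simulate_dataset, simulate_platform_pair

SMALL_SIM = SimConfig(n_per_subtype=10, n_genes=300, seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """300-gene, 40-sample cohort with 10 up + 10 down markers per subtype."""
    return simulate_dataset(SMALL_SIM)


@pytest.fixture(scope="session")
def cohort_pair():
    """Two independent 40-sample draws from one ground truth (no shift)."""
    cfg = SimConfig(
        n_per_subtype=10, n_genes=300, seed=2,
        platform_shift_sd=0.0, platform_b_gene_fraction=1.0,
    )
    return simulate_platform_pair(cfg)


@pytest.fixture(scope="session")
def trained_model(cohort_pair):
    mat_a, _, labels, _ = cohort_pair
    return train_on_dataset(
        mat_a, labels.subset(mat_a.sample_ids), source="cohortA"
    )


@pytest.fixture
def tiny_log2_matrix():
    """Deterministic 6-gene, 8-sample log2 matrix, two subtypes."""
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        rng.normal(7, 1, (6, 8)),
        index=[f"G{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(8)],
    )
    mat = ExpressionMatrix(data, scale="log2")
    labels = LabelSet(list(data.columns), ["SHH"] * 4 + ["WNT"] * 4)
    return mat, labels


def make_expression(values, genes=None, samples=None, scale="linear"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), scale=scale
    )
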