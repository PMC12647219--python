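import numpy as np
import pandas as pd
import pytest

import gbacorr as g


@pytest.fixture
def tiny_abundance() -> g.AbundanceMatrix:
    """3 proteins × 4 samples with two MISSING cells."""
    frame = pd.DataFrame(
        [[1.0, 2.0, np.nan, 4.0],
         [5.0, np.nan, 7.0, 8.0],
         [9.0, 10.0, 11.0, 12.0]],
        index=["P1", "P2", "P3"],
        columns=["S1", "S2", "S3", "S4"],
    )
    return g.AbundanceMatrix(frame)


@pytest.fixture
def seeded_matrix() -> g.AbundanceMatrix:
    """30 proteins × 20 samples of positive intensities, ~15% missing."""
    rng = np.random.default_rng(42)
    values = np.exp2(rng.normal(20.0, 2.0, size=(30, 20)))
    mask = rng.random(size=values.shape) < 0.15
    values[mask] = np.nan
    frame = pd.DataFrame(
        values,
        index=[f"P{i:02d}" for i in range(30)],
        columns=[f"S{j:02d}" for j in range(20)],
    )
    return g.AbundanceMatrix(frame)


@pytest.fixture(scope="session")
def planted_cohort():
    """The planted-module study cohort: 1000 proteins × 500 samples, one
    size-8 module at target Spearman 0.7 containing the query, 20%
    abundance-dependent missingness, fixed seed."""
    spec = g.CohortSpec(
        n_proteins=1000, n_samples=500, modules=[(8, 0.7)],
        missingness=g.MissingnessSpec(global_rate=0.2, detection_slope=1.0),
        seed=1,
    )
    matrix, truth = g.generate_cohort(spec)
    return matrix, truth


@pytest.fixture(scope="session")
def planted_corr(planted_cohort):
    matrix, truth = planted_cohort
    return g.correlation_matrix(matrix), truth
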