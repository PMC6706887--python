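import numpy as np
import pandas as pd
import pytest

from mrcps.io import ExpressionMatrix, zscore
from mrcps.synthetic import CohortConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Compact aligned-signal cohort shared across module tests."""
    cfg = CohortConfig(
        n_patients=100,
        n_genes_per_platform=120,
        n_shared_genes=120,
        n_modules=3,
        module_size_range=(10, 15),
        factor_loading=0.85,
        noise_sd=0.2,
        n_subgroups=2,
        subgroup_hazards=(0.06, 0.015),
        censor_rate=0.2,
        stage_confusion=0.0,
        seed=7,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def small_zscored(small_cohort):
    return zscore(small_cohort.expr_a)


def make_expression(values, genes=None, samples=None, **kw) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), **kw)
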