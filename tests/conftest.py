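import warnings

import numpy as np
import pandas as pd
import pytest

from dmcortexome.io import ExpressionMatrix, PsiMatrix
from dmcortexome.simulate import CohortConfig, simulate_cohort

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (8 unaffected + 21 affected, 130 responsive
    + 2000 null exons), seed 1; shared read-only across tests."""
    return simulate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A fast, reduced cohort for tests that re-run the whole stack."""
    cfg = CohortConfig(seed=7, n_null_exons=200, n_genes=600,
                       n_specific_per_type=60, n_background_events=100)
    return cfg, simulate_cohort(cfg)


def make_psi(values, groups, events=None, samples=None) -> PsiMatrix:
    values = np.asarray(values, dtype=float)
    events = events or [f"e{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return PsiMatrix(pd.DataFrame(values, index=events, columns=samples),
                     dict(zip(samples, groups)))


def make_expr(values, groups, genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            dict(zip(samples, groups)))
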