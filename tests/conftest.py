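import numpy as np
import pandas as pd
import pytest

from lncpair.io import ExpressionMatrix
from lncpair.synthetic import Cohort, CohortConfig, generate_cohort


def make_expression(values, gene_ids, sample_ids, groups=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    if groups is None:
        groups = {s: "tumor" for s in sample_ids}
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        sample_group=groups,
    )


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """A compact planted cohort reused by tests that only need structure."""
    cfg = CohortConfig(
        n_tumor=150,
        n_normal=40,
        n_lncrna=60,
        n_immune_gene=10,
        n_noise_gene=30,
        n_corr_lncrna=20,
        n_de_lncrna=16,
        n_signal_pairs=4,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    """The generator's default study conditions (400 tumors, 8 signal pairs)."""
    return generate_cohort(CohortConfig(seed=11))
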