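import logging

import numpy as np
import pytest

from sectormix.core_io import PeptideMatrix
from sectormix.synthetic import SyntheticConfig, generate

logging.getLogger("sectormix").setLevel(logging.WARNING)


def make_matrix(values, observed=None, groups=None, match_type=None):
    """Build a PeptideMatrix from a (possibly NaN-holed) array."""
    values = np.asarray(values, dtype=float)
    if observed is None:
        observed = np.isfinite(values)
    n, d = values.shape
    return PeptideMatrix(
        values=values,
        observed=np.asarray(observed, dtype=bool),
        peptide_ids=[f"pep{i}" for i in range(n)],
        sample_ids=[f"s{j}" for j in range(d)],
        groups=groups,
        match_type=match_type,
    )


@pytest.fixture
def tiny_matrix():
    """5 peptides x 4 samples with 3 missing cells."""
    vals = np.array(
        [
            [10.0, 11.0, 10.5, 12.0],
            [20.0, np.nan, 19.5, 20.5],
            [15.0, 15.5, np.nan, 16.0],
            [8.0, 8.5, 9.0, np.nan],
            [25.0, 24.0, 26.0, 25.5],
        ]
    )
    return make_matrix(vals)


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic dataset, shared across read-only tests."""
    return generate(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def rank2_dataset():
    """Low-noise rank-2 data with 10% random missingness (500 x 40)."""
    cfg = SyntheticConfig(
        n_peptides=500, n_samples=40, n_factors=2, factor_sd=1.0,
        noise_sd=0.2, mcar_rate=0.10, mnar_midpoint=0.0, mnar_steepness=1.0,
        peptide_effect_sd=0.0, seed=7,
    )
    ds = generate(cfg)
    return ds.observed.drop_all_missing_peptides()
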