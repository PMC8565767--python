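"""Shared fixtures: one small synthetic landscape and fitted model reused
across the GAM, validation and decomposition tests (session-scoped because
simulation and fitting dominate test runtime)."""

import numpy as np
import pandas as pd
import pytest

from firegam.features import COVARIATES, build_design_table
from firegam.gam import SmoothTermSpec, fit_binomial_gam
from firegam.sampling import poisson_disk_sample
from firegam.synthetic import SyntheticConfig, generate_dataset

SMALL_YEARS = (1970, 1994)


def small_config(seed=5, **overrides):
    kw = dict(n_rows=32, n_cols=32, year_start=SMALL_YEARS[0],
              year_end=SMALL_YEARS[1], seed=seed)
    kw.update(overrides)
    return SyntheticConfig(**kw)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config())


@pytest.fixture(scope="session")
def small_panel(small_dataset):
    return small_dataset[0]


@pytest.fixture(scope="session")
def small_history(small_dataset):
    return small_dataset[1]


@pytest.fixture(scope="session")
def small_table(small_dataset):
    panel, history = small_dataset
    years = np.arange(SMALL_YEARS[0], SMALL_YEARS[1] + 1)
    return build_design_table(panel, history, years)


@pytest.fixture(scope="session")
def small_train(small_table):
    """Poisson-disk-thinned training rows (2-km spacing keeps enough rows
    for stable fits at this grid size)."""
    candidates = (small_table[["pixel_id", "row", "col"]]
                  .drop_duplicates("pixel_id").reset_index(drop=True))
    sample = poisson_disk_sample(candidates, min_distance_km=2.0, seed=17)
    return small_table[small_table["pixel_id"].isin(set(sample.pixel_id))]


@pytest.fixture(scope="session")
def term_specs():
    return [SmoothTermSpec(name) for name in COVARIATES]


@pytest.fixture(scope="session")
def small_model(small_table, term_specs):
    """Fitted on the full (unthinned) table: the shared model fixture
    favors estimation quality; sampling behavior is tested separately."""
    return fit_binomial_gam(small_table, term_specs, lambda_rule=1.0)
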