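import warnings

import numpy as np
import pandas as pd
import pytest

from dietrec.catalog import default_catalog
from dietrec.intake import filter_by_energy
from dietrec.ratings import quintile_ratings
from dietrec.synthetic import default_config, generate_cohort


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture()
def small_ratings():
    """Deterministic 6 users x 5 items matrix with scattered missing cells."""
    data = np.array([
        [5.0, 4.0, np.nan, 2.0, 1.0],
        [4.0, 5.0, 3.0, np.nan, 2.0],
        [1.0, 2.0, 4.0, 5.0, np.nan],
        [np.nan, 1.0, 5.0, 4.0, 5.0],
        [3.0, np.nan, 2.0, 3.0, 4.0],
        [2.0, 3.0, np.nan, 1.0, 3.0],
    ])
    return pd.DataFrame(
        data,
        index=[f"u{i}" for i in range(6)],
        columns=[f"g{j}" for j in range(5)],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-participant default-archetype cohort (fixed seed)."""
    table, labels = generate_cohort(default_config(n_participants=400, seed=11))
    return table, labels


@pytest.fixture(scope="session")
def small_cohort_ratings(small_cohort, catalog):
    """Energy-filtered ratings + labels for the small cohort."""
    table, labels = small_cohort
    kept, _ = filter_by_energy(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        R = quintile_ratings(kept, catalog)
    return R, labels.reindex(kept.index)
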