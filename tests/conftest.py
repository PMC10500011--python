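import numpy as np
import pandas as pd
import pytest

from snfomics import CohortConfig, OmicMatrix, simulate_cohort
from snfomics.synthetic import DEFAULT_CELL_TYPES

DEFAULT_SEED = 123


def make_matrix(values, layer="mrna", is_log=True, features=None, samples=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return OmicMatrix(layer, pd.DataFrame(values, index=features, columns=samples), is_log=is_log)


def equal_fraction_config(**overrides):
    """Config with identical cell-type mixing in both groups."""
    eq = {g: dict(zip(DEFAULT_CELL_TYPES, (0.65, 0.10, 0.15, 0.10))) for g in ("group1", "group2")}
    base = dict(celltype_fractions=eq)
    base.update(overrides)
    return CohortConfig(**base)


def weak_effect_config(**overrides):
    """Configuration where each single layer only weakly separates the
    groups (single-layer spectral ARI < 0.7), so the benefit of fusing
    layers is measurable."""
    base = dict(n_samples=40, effect_size=0.7, frac_de=0.05, ratio_shift_delta=0.0)
    base.update(overrides)
    return equal_fraction_config(**base)


@pytest.fixture(scope="session")
def default_cohort():
    """One discovery-design cohort (28 samples, defaults) shared by tests."""
    return simulate_cohort(CohortConfig(), seed=DEFAULT_SEED)
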