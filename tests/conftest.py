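import numpy as np
import pytest

from oametab.io import load_compound_library, bundled_library_path, load_selected_variables
from oametab.simulate import SimulationConfig, small_config, generate_study


@pytest.fixture(scope="session")
def library():
    return load_compound_library(bundled_library_path())


@pytest.fixture(scope="session")
def printed_variables():
    """The bundled VIP-selected variable lists keyed by comparison."""
    return {c: load_selected_variables(c) for c in ("t28", "t56", "t84")}


@pytest.fixture(scope="session")
def small_study():
    """Small QC-dense study with the default 1% discriminant fraction."""
    return generate_study(small_config(seed=1))


@pytest.fixture(scope="session")
def strong_study():
    """Small study with a denser planted set (~10 discriminant features)."""
    return generate_study(small_config(seed=1, fraction_discriminant=0.05))


@pytest.fixture()
def strong_design(strong_study):
    """Samples x variables log10 matrix restricted to clean features, plus labels."""
    pos, neg, sheet, truth = strong_study
    return _paired_design(pos, neg, sheet)


def _paired_design(pos, neg, sheet):
    import pandas as pd

    from oametab.volcano import impute_half_min

    pairs = sheet.pairs("T0", "T28")
    sample_ids = list(pairs["early"]) + list(pairs["late"])
    stacked = pd.concat([pos.intensities[sample_ids], neg.intensities[sample_ids]])
    X = np.log10(impute_half_min(stacked).to_numpy(dtype=float)).T
    y = np.array([-1.0] * len(pairs), dtype=float)
    y = np.concatenate([y, -y])
    return X, y, list(stacked.index)


@pytest.fixture(scope="session")
def null_xy():
    """Factory for y-independent Gaussian data (20 samples x 50 variables)."""

    def make(seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 50))
        y = np.array([0] * 10 + [1] * 10)
        return X, y

    return make
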