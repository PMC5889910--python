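import dataclasses

import numpy as np
import pytest

from bindspec import HSA, SyntheticTruth, generate_quenching


@pytest.fixture
def hsa_20uM():
    """HSA at the 20 uM working concentration used for CD."""
    return dataclasses.replace(HSA, concentration=20e-6)


@pytest.fixture
def micromolar_grid():
    """A 1-10 uM quencher grid in mol/L."""
    return np.arange(1, 11, dtype=float) * 1e-6


@pytest.fixture
def noiseless_static_series():
    """Exact titration from the single-site binding model, K=3.74e6, n=1.1."""
    truth = SyntheticTruth(mode="static_binding", k_true=3.74e6, n_true=1.1,
                           f0_true=1000.0, noise_rel=0.0)
    return generate_quenching(truth), truth
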