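import numpy as np
import pytest

from nmrkin.model import RateParameters


@pytest.fixture
def default_params() -> RateParameters:
    """Moderate, well-conditioned alternate-state parameters."""
    return RateParameters(
        k1=0.2, k_off=10.0, kcat_E=0.4, kcat_Estar=0.1,
        kE_fwd=0.004, kE_rev=0.002, kES_fwd=0.003, kES_rev=0.001,
    )


@pytest.fixture
def apo_demethylation_params() -> RateParameters:
    """Micro-rates whose derived observables match the APO demethylation row."""
    from nmrkin.synth import CONDITIONS, invert_observables

    return invert_observables(**CONDITIONS[("demethylation", "APO")])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
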