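import numpy as np
import pytest

from cuehgf import cohort as cohort_mod
from cuehgf import design


@pytest.fixture(scope="session")
def canonical_seq():
    return design.assign_timing(design.generate_trial_sequence(),
                                seed=design.CANONICAL_SEED)


@pytest.fixture(scope="session")
def u(canonical_seq):
    return canonical_seq["validity"].to_numpy()


def reduced_fwd(**overrides) -> cohort_mod.ErpForwardModel:
    """Forward model at 125 Hz for fast replicated simulations."""
    fwd = cohort_mod.ErpForwardModel(**overrides)
    fwd.srate_hz = 125.0
    return fwd


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
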