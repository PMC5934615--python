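import numpy as np
import pytest

from cytrcollapse import calorimetry


@pytest.fixture(scope="session")
def vb_params():
    """Reference variable-barrier parameter set of the CytR thermogram fit."""
    return calorimetry.VBParams(
        sum_alpha=1554.9, beta=-173.7, T0=291.7, f=0.535
    )


@pytest.fixture(scope="session")
def dsc_T_grid():
    return np.arange(278.0, 374.0, 1.0)
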