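import warnings

import numpy as np
import pytest

from ketopk import reference_parameters
from ketopk.pk_fit import CalibrationInfeasibleWarning
from ketopk.synthetic import EXAMPLE_TRUTH


@pytest.fixture(scope="session")
def reference_params():
    """Model parameters calibrated to the published 2 g / 4 g peak summaries.

    The calibration is over-constrained (four peak values, three absorption
    parameters) and warns about its residual; that is expected and the
    warning is silenced here.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", CalibrationInfeasibleWarning)
        return reference_parameters(seed=0)


@pytest.fixture(scope="session")
def example_truth():
    return EXAMPLE_TRUTH


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)
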