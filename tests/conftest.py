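import numpy as np
import pytest

# Reference moment table for the normal-shift p-value model and its
# step-function calibrations: delta -> (mean, sd, f, g, breakpoint,
# f_simplified, 1/f_simplified), all printed to 3 decimals.
MOMENT_TABLE = {
    0.2: (0.444, 0.286, 1.249, 0.795, 0.451, 1.127, 0.888),
    0.5: (0.362, 0.274, 1.728, 0.555, 0.380, 1.382, 0.724),
    1.0: (0.240, 0.236, 2.937, 0.288, 0.269, 2.086, 0.480),
    2.0: (0.079, 0.130, 9.061, 0.059, 0.105, 6.357, 0.157),
    3.0: (0.017, 0.049, 37.143, 0.007, 0.027, 29.503, 0.034),
}


@pytest.fixture
def rng():
    return np.random.default_rng(20161010)
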