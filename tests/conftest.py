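import numpy as np
import pytest

from tacsnet import build_population, simulate
from tacsnet.metrics import psd


@pytest.fixture(scope="session")
def default_node():
    """Single-region model with the shipped alpha-band parameters."""
    return build_population()


@pytest.fixture(scope="session")
def baseline_run(default_node):
    """One unstimulated 12 s run of the default node."""
    return simulate(default_node, None, duration_s=12.0, seed=0)


@pytest.fixture(scope="session")
def natural_freq(default_node):
    peaks = [
        psd(simulate(default_node, None, 12.0, seed=s).lfp[0], 0.1).peak_freq
        for s in (0, 1, 2)
    ]
    return float(np.median(peaks))
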