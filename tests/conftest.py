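import warnings

import pandas as pd
import pytest

from methtf.diff import differential_methylation
from methtf.reins import TFBindingCatalog, merge_intervals
from methtf.simulate import make_config, simulate_all


@pytest.fixture(scope="session")
def tiny_data():
    """A small simulated dataset shared by unit tests (read-only)."""
    return simulate_all(make_config("tiny", seed=1))


@pytest.fixture(scope="session")
def tiny_diff(tiny_data):
    return differential_methylation(tiny_data.beta, tiny_data.sheet)


@pytest.fixture(scope="session")
def tiny_catalog(tiny_data):
    return TFBindingCatalog(
        {lbl: merge_intervals(ivs) for lbl, _, ivs in tiny_data.tf_peaks if ivs}
    )


@pytest.fixture()
def suppress_small_state_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
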