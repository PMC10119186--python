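import numpy as np
import pandas as pd
import pytest

from ajburden import synth


@pytest.fixture(scope="session")
def common_panel():
    return synth.simulate_reference_panels(2000, 0.1, seed=7)


@pytest.fixture(scope="session")
def small_study():
    """One modest null-free study reused by read-only tests."""
    spec = synth.SimSpec(
        n_cases=400, n_controls=400, n_markers_rare=2000, n_genes=200,
        risk_genes=("G0001", "G0002"), risk_carrier_or=3.0, seed=5,
    )
    return synth.generate_study(spec)


@pytest.fixture(scope="session")
def null_study():
    """A null cohort (carrier odds ratio 1) for calibration checks."""
    spec = synth.SimSpec(
        n_cases=400, n_controls=400, n_markers_rare=2000, n_genes=200,
        risk_genes=(), risk_carrier_or=1.0, seed=6,
    )
    return synth.generate_study(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
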