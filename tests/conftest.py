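import numpy as np
import pytest
from scipy import stats

from halovalid.datamodel import default_method_path, read_method_definition


@pytest.fixture(scope="session")
def method():
    """Bundled method definition: (panel, srm_certified, ecoscale ledger)."""
    return read_method_definition(default_method_path())


@pytest.fixture(scope="session")
def panel(method):
    return method[0]


@pytest.fixture(scope="session")
def srm_certified(method):
    return method[1]


@pytest.fixture(scope="session")
def panel_map(panel):
    return {a.name: a for a in panel}


def sd_band(sd_true: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Two-sided sampling band for a sample SD of n normal draws."""
    alpha = 1.0 - conf
    lo = sd_true * np.sqrt(stats.chi2.ppf(alpha / 2, n - 1) / (n - 1))
    hi = sd_true * np.sqrt(stats.chi2.ppf(1 - alpha / 2, n - 1) / (n - 1))
    return float(lo), float(hi)
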