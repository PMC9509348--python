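import numpy as np
import pytest

from perceptgene.model import PerceptgeneParams


@pytest.fixture
def rng():
    return np.random.default_rng(20220924)


@pytest.fixture
def fig1h_params():
    """Sigmoid perceptgene with the measured IPTG/aTc weights."""
    return PerceptgeneParams(
        input_names=("IPTG", "aTc"),
        weights=(0.3375, 0.4375),
        input_scales=(1.25, 0.75),
        bias=1.0 / 19.0,
        hill=2.2,
        basal=0.045,
    )
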