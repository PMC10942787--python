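import numpy as np
import pytest

from spikemux.io import Triplet
from spikemux.simulate import RegimeSpec, simulate_population


@pytest.fixture
def well_separated_triplet():
    """Sharply informed rates near 20 and 5 with a clearly bimodal AB sample."""
    rng = np.random.default_rng(1234)
    a = rng.poisson(20, 20)
    b = rng.poisson(5, 20)
    ab = np.empty(16, dtype=int)
    ab[0::2] = rng.poisson(20, 8)
    ab[1::2] = rng.poisson(5, 8)
    return Triplet("fix-mix", "A|B", a, b, ab)


@pytest.fixture
def regime_population():
    """Small labelled population covering the four categories."""
    specs = []
    for regime in ("mixture", "intermediate", "single_A", "outside_high"):
        specs += [RegimeSpec(regime=regime) for _ in range(5)]
    return simulate_population(specs, master_seed=99)
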