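import numpy as np
import pytest

from cowbw.simulate import HerdConfig, generate_herd


ZERO_NOISE = {k: 0.0 for k in ("sbw", "ebw", "gu", "ut", "ud", "bw")}


@pytest.fixture(scope="session")
def zero_noise_herd():
    """Default study-design herd with the noise switched off: observed values
    equal the latent truths."""
    config = HerdConfig(noise_cv=dict(ZERO_NOISE), seed=123)
    return generate_herd(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20150320)
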