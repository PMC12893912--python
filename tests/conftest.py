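import numpy as np
import pytest

from mesoswim import CantileverModel, GeneratorConfig


@pytest.fixture(scope="session")
def config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def swim_cantilever():
    """A 10 nN/um cantilever with the study-average drag coefficient."""
    from mesoswim.synthetic import MK_PRODUCT

    k = 0.01
    return CantileverModel(k=k, b=35.5e-6, m_eff=MK_PRODUCT / k)


def make_ringdown_trace(A, phi, xi, w0, sample_rate, duration, noise_sd=0.0,
                        seed=None):
    """Exact underdamped ringdown samples in the 4-parameter form."""
    from mesoswim.force import DeflectionTrace

    t = np.arange(int(duration * sample_rate)) / sample_rate
    wd = w0 * np.sqrt(1 - xi**2)
    x = A * np.exp(-xi * w0 * t) * np.sin(wd * t + phi)
    if noise_sd:
        x = x + np.random.default_rng(seed).normal(0, noise_sd, len(x))
    return DeflectionTrace(sample_rate=sample_rate, deflection=x)
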