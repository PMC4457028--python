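import numpy as np
import pytest

from locipair import (
    generate_nucleus_stack,
    meristematic_model,
)


@pytest.fixture(scope="session")
def clean_meristematic():
    """Noiseless, unjittered meristematic stack at true separation 3.5 μm."""
    model = meristematic_model(noise=False, size_jitter_sd=0.0)
    stack, truth = generate_nucleus_stack(model, separation_override=3.5, seed=1234)
    return model, stack, truth


@pytest.fixture(scope="session")
def noisy_meristematic():
    """Default (noisy, jittered) meristematic stack."""
    model = meristematic_model()
    stack, truth = generate_nucleus_stack(model, seed=77)
    return model, stack, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
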