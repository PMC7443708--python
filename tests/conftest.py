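import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def world():
    """Default desk-scale synthetic world shared across tests."""
    from washmap.synthetic import WorldConfig, generate_world

    return generate_world(WorldConfig(seed=7))


@pytest.fixture(scope="session")
def constant_truth_world():
    """World whose true category surface is constant (0.4, 0.3, 0.2, 0.1)
    at every cell and year — an analytic sampling oracle."""
    from washmap.ordinal import conditional_from_category
    from washmap.synthetic import WorldConfig, generate_world

    w = generate_world(WorldConfig(seed=11))
    target = np.array([0.4, 0.3, 0.2, 0.1])
    w.true_category = np.broadcast_to(
        target[:, None, None], w.true_category.shape
    ).copy()
    w.true_conditional = conditional_from_category(w.true_category)
    return w
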