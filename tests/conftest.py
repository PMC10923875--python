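import numpy as np
import pytest

from brainflex import (
    StructuralConnectome,
    generate_synthetic_connectome,
    generate_synthetic_template,
)


@pytest.fixture
def ring5():
    """Unit-weight ring of 5 nodes."""
    w = np.zeros((5, 5))
    for i in range(5):
        w[i, (i + 1) % 5] = w[(i + 1) % 5, i] = 1.0
    return StructuralConnectome(w)


@pytest.fixture
def small_G():
    """Modular 20-node synthetic connectome."""
    return generate_synthetic_connectome(20, 4, seed=11)


@pytest.fixture
def small_template():
    return generate_synthetic_template(20, 4, seed=12)
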