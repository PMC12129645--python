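import numpy as np
import pytest

from nusquant.noesy_sim import SpinSystem, make_default_spin_system


@pytest.fixture(scope="session")
def sys12() -> SpinSystem:
    return make_default_spin_system()


@pytest.fixture(scope="session")
def sys2() -> SpinSystem:
    d = np.array([[0.0, 1.78], [1.78, 0.0]])
    return SpinSystem(("H1", "H2"), d, ("H1", "H2"))


@pytest.fixture(scope="session")
def sys5() -> SpinSystem:
    """Well-separated five-proton system with distances up to 3.8 A."""
    d = np.array(
        [
            [0.00, 1.78, 2.50, 3.20, 3.80],
            [1.78, 0.00, 2.20, 2.90, 3.50],
            [2.50, 2.20, 0.00, 2.60, 3.10],
            [3.20, 2.90, 2.60, 0.00, 2.40],
            [3.80, 3.50, 3.10, 2.40, 0.00],
        ]
    )
    return SpinSystem(("H1", "H2", "H3", "H4", "H5"), d, ("H1", "H2"))
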