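import numpy as np
import pytest

from spatmetrics import Landscape, PointPattern, simulate_csr


@pytest.fixture
def toy_pattern() -> PointPattern:
    """Three points in a 2 x 2 window; quadrat counts at side 1 are {1,1,1,0}."""
    return PointPattern(
        np.array([(0.5, 0.5), (1.5, 0.5), (1.5, 1.5)]), Landscape(2.0, 2.0)
    )


@pytest.fixture
def csr_pattern() -> PointPattern:
    """A moderate CSR pattern in a 50 x 50 window (seeded)."""
    return simulate_csr(500, Landscape(50.0, 50.0), seed=42)


@pytest.fixture
def bci_window() -> Landscape:
    """The 500 m x 1000 m census-plot window used by the simulation studies."""
    return Landscape(500.0, 1000.0)
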