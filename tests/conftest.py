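import numpy as np
import pytest

from sparsemet.markers import MarkerMatrix, grm_vanraden
from sparsemet.synthetic import simulate_markers


@pytest.fixture(scope="session")
def small_markers() -> MarkerMatrix:
    """Complete 60-line x 400-marker dosage matrix."""
    return simulate_markers(60, 400, seed=11)


@pytest.fixture(scope="session")
def small_kinship(small_markers):
    return grm_vanraden(small_markers)


@pytest.fixture
def toy_markers() -> MarkerMatrix:
    """4 lines x 3 markers with one missing call (hand-checkable)."""
    values = np.array(
        [
            [0.0, 2.0, 0.0],
            [1.0, np.nan, 0.0],
            [2.0, 1.0, 0.0],
            [1.0, 1.0, 0.0],
        ]
    )
    return MarkerMatrix(values, [f"L{i}" for i in range(1, 5)], ["M1", "M2", "M3"])
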