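import numpy as np
import pytest

from ellipack import CellParameters, CrystalCentroids


@pytest.fixture
def rng():
    return np.random.default_rng(20250928)


@pytest.fixture
def cubic_cell():
    return CellParameters(0.5, 0.5, 0.5, 90.0, 90.0, 90.0)


@pytest.fixture
def triclinic_cell():
    return CellParameters(0.4, 0.5, 0.6, 80.0, 95.0, 100.0)


@pytest.fixture
def cubic_p_crystal(cubic_cell):
    return CrystalCentroids(cell=cubic_cell, fractional=np.zeros((1, 3)))


def random_cell(rng, lengths=(0.3, 1.2), angles=(70.0, 110.0), max_cond=10.0):
    """Draw a well-conditioned random cell (shared helper)."""
    from ellipack.geometry import cell_matrix

    while True:
        cell = CellParameters(
            a=rng.uniform(*lengths), b=rng.uniform(*lengths), c=rng.uniform(*lengths),
            alpha=rng.uniform(*angles), beta=rng.uniform(*angles), gamma=rng.uniform(*angles),
        )
        try:
            if np.linalg.cond(cell_matrix(cell)) <= max_cond:
                return cell
        except ValueError:
            continue
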