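import numpy as np
import pytest

from xrfquant.simulate import DetectorModel, MatrixProfile
from xrfquant.spectra import EnergyGrid, RegionSpec, Spectrum


@pytest.fixture
def detector() -> DetectorModel:
    return DetectorModel()


@pytest.fixture
def matrix_unit2() -> MatrixProfile:
    return MatrixProfile(intrinsic_as=87.82, intrinsic_pb=3.19)


@pytest.fixture
def regions() -> RegionSpec:
    return RegionSpec([(10.35, 10.70), (12.40, 12.85)])


@pytest.fixture
def small_spectrum() -> Spectrum:
    grid = EnergyGrid(start_keV=10.0, step_keV=0.01, n_channels=300)
    rng = np.random.default_rng(7)
    bg = np.full(300, 50.0)
    return Spectrum(grid=grid, total_counts=rng.poisson(60, 300).astype(float),
                    background_counts=bg, standard_id="S1", pellet_id="P1",
                    repeat_id="R1")
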