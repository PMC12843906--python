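import numpy as np
import pytest

from nirpls.spectral_io import SpectraSet, WavenumberGrid, canonical_grid


@pytest.fixture(scope="session")
def grid() -> WavenumberGrid:
    return canonical_grid()


@pytest.fixture()
def small_grid() -> WavenumberGrid:
    return WavenumberGrid(9000.0 - 4.0 * np.arange(10))


@pytest.fixture()
def small_spectra(small_grid) -> SpectraSet:
    rng = np.random.default_rng(42)
    n = 6
    return SpectraSet(
        sample_ids=np.repeat([f"S{i}" for i in range(n // 2)], 2),
        replicate_ids=np.tile([1, 2], n // 2),
        absorbance=rng.uniform(0.1, 1.0, size=(n, small_grid.n_points)),
        grid=small_grid,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic calibration/validation dataset (seeded)."""
    from nirpls.synthetic_data import simulate_dataset

    return simulate_dataset(seed=11)


@pytest.fixture(scope="session")
def noiseless_dataset():
    from nirpls.synthetic_data import NoiseModel, simulate_dataset

    return simulate_dataset(seed=11, noise=NoiseModel.noiseless())
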