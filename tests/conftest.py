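import numpy as np
import pytest

from collagenmap.chemometrics import fit_calibration
from collagenmap.preprocess import PreprocessRecipe
from collagenmap.synthetic import SyntheticConfig, simulate_calibration


@pytest.fixture(scope="session")
def config():
    return SyntheticConfig()


@pytest.fixture(scope="session")
def quiet_config():
    """Generator with scatter and noise switched off: deterministic spectra."""
    return SyntheticConfig(
        scatter_gain_range=(1.0, 1.0),
        scatter_offset_range=(0.0, 0.0),
        noise_sd=0.0,
        powder_smooth_sd=0.0,
        fragment_smooth_sd=0.0,
    )


@pytest.fixture(scope="session")
def calibration(config):
    samples, truth = simulate_calibration(config=config, seed=0)
    return samples, truth


@pytest.fixture(scope="session")
def fitted(config, calibration):
    samples, _ = calibration
    recipe = PreprocessRecipe()
    model, cv = fit_calibration(
        samples, config.wavelength_grid, recipe=recipe, seed=0
    )
    return model, cv


def make_cube(rows=4, cols=3, n_bands=5, seed=0, kind="raw"):
    """Tiny arbitrary cube for I/O tests."""
    from collagenmap.io import SpectralCube

    rng = np.random.default_rng(seed)
    data = rng.uniform(0.1, 0.9, size=(rows, cols, n_bands))
    wl = 1000.0 + 5.6 * np.arange(n_bands)
    return SpectralCube(data=data, wavelengths=wl, kind=kind)


@pytest.fixture
def tiny_cube():
    return make_cube()
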