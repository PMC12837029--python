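import numpy as np
import pytest

from mixcal import calibration, designs, spectra_sim


@pytest.fixture(scope="session")
def space():
    return designs.DesignSpace([("AZM", 10.0, 30.0), ("MPM", 10.0, 30.0)])


@pytest.fixture(scope="session")
def library():
    return spectra_sim.default_band_library()


@pytest.fixture(scope="session")
def grid():
    return spectra_sim.default_grid()


@pytest.fixture(scope="session")
def factorial_design(space):
    return designs.factorial_calibration_design(space)


@pytest.fixture(scope="session")
def clean_calibration(factorial_design, library, grid):
    """Noiseless 25-mixture calibration set, trimmed to the modeling window."""
    s = spectra_sim.simulate_mixtures(factorial_design, library, grid)
    return spectra_sim.trim_wavelengths(s, 200.0, 335.0)


@pytest.fixture(scope="session")
def noisy_calibration(factorial_design, library, grid):
    """Default-noise 25-mixture calibration set, trimmed."""
    noise = spectra_sim.NoiseModel(seed=42)
    s = spectra_sim.simulate_mixtures(factorial_design, library, grid, noise)
    return spectra_sim.trim_wavelengths(s, 200.0, 335.0)


@pytest.fixture(scope="session")
def sobol_validation(space, library, grid):
    """Default-noise 13-mixture Sobol validation set, trimmed."""
    v = designs.sobol_design(13, space)
    s = spectra_sim.simulate_mixtures(v, library, grid, spectra_sim.NoiseModel(seed=99))
    return spectra_sim.trim_wavelengths(s, 200.0, 335.0)


@pytest.fixture(scope="session")
def noisy_pls(noisy_calibration):
    lv, curve = calibration.select_lv_loocv(
        noisy_calibration.absorbance, noisy_calibration.concentrations, 5)
    m = calibration.fit_pls(noisy_calibration.absorbance, noisy_calibration.concentrations, lv)
    m.rmsecv_curve = curve
    return m


def make_linear_problem(n=20, p=6, q=2, seed=0, noise=0.0):
    """Y exactly (or nearly) linear in X, for least-squares oracles."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, p))
    b = rng.normal(size=(p, q))
    y = x @ b + 1.5 + noise * rng.normal(size=(n, q))
    return x, y
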