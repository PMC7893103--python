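import numpy as np
import pytest
from hypothesis import settings

from circlight import SPD, WavelengthGrid, build_function_set, generate_spd

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid()


@pytest.fixture(scope="session")
def fns(grid):
    return build_function_set(grid)


@pytest.fixture(scope="session")
def fns_cie(grid):
    return build_function_set(grid, melanopsin_variant="cie")


@pytest.fixture(scope="session")
def illuminant_a_1000lx(grid, fns):
    from circlight import scale_spd_to

    spd = generate_spd("illuminant_a", grid=grid)
    return scale_spd_to(spd, "photopic_lux", 1000.0, fns)


def random_spd(rng: np.random.Generator, grid: WavelengthGrid) -> SPD:
    """A smooth random stimulus: a few Gaussian bands plus optional broadband."""
    wl = grid.wavelengths
    values = np.zeros(grid.n)
    for _ in range(rng.integers(1, 5)):
        center = rng.uniform(390.0, 720.0)
        width = rng.uniform(8.0, 150.0)
        weight = rng.uniform(0.05, 2.0)
        values += weight * np.exp(-((wl - center) ** 2) / (2.0 * width**2))
    if rng.random() < 0.3:
        values += rng.uniform(0.001, 0.05)
    scale = 10.0 ** rng.uniform(-3.0, 1.0)
    return SPD(grid, values * scale, label="random")


def monochromatic(grid: WavelengthGrid, wavelength: float, total_w_m2: float = 1.0) -> SPD:
    """All power concentrated in the single grid bin at `wavelength`."""
    values = np.zeros(grid.n)
    idx = int(round((wavelength - grid.start_nm) / grid.step_nm))
    values[idx] = total_w_m2 / grid.step_nm
    return SPD(grid, values, label=f"mono_{wavelength:g}")
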