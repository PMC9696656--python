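"""Shared fixtures: the published reference values and handy configs."""

import pytest

from pepnetms import Peak, Spectrum, subarmigeride
from pepnetms.simulate import SimulationConfig

#: Published product-ion table for compound A: (observed m/z, reported ppm
#: error, cation formula string).  These printed values are inputs to the
#: golden tests.
TABLE2_ROWS = [
    (857.4914, 0.7, "C46H65N8O8"),
    (716.4146, -2.2, "C39H54N7O6"),
    (699.3862, 0.4, "C39H51N6O6"),
    (671.3931, -2.3, "C38H51N6O5"),
    (630.3298, -1.9, "C35H44N5O6"),
    (533.2763, -0.8, "C30H37N4O5"),
    (505.2813, -0.8, "C29H37N4O4"),
    (489.2506, -1.9, "C28H33N4O4"),
    (472.2919, 0.0, "C25H38N5O4"),
    (455.2659, -1.4, "C25H35N4O4"),
    (392.1971, -0.6, "C23H26N3O3"),
    (386.2075, -0.2, "C21H28N3O4"),
    (375.1700, 0.9, "C23H23N2O3"),
    (358.2129, -1.0, "C20H28N3O3"),
    (342.1805, 2.2, "C19H24N3O3"),
    (325.2232, 0.6, "C16H29N4O3"),
    (308.1966, 0.8, "C16H26N3O3"),
    (245.1282, 1.2, "C14H17N2O2"),
    (239.1387, 1.4, "C12H19N2O3"),
    (228.1702, 1.8, "C11H22N3O2"),
    (217.1332, 1.4, "C13H17N2O"),
    (211.1437, 1.7, "C11H19N2O2"),
    (195.1124, 1.8, "C10H15N2O2"),
    (183.1485, 3.5, "C10H19N2O"),
    (167.1160, 11.2, "C9H15N2O"),
    (120.080173, 5.0, "C8H10N"),
    (86.096342, 1.0, "C5H12N"),
    (70.064503, 8.9, "C4H8N"),
]


@pytest.fixture(scope="session")
def compound_a():
    return subarmigeride("A")


@pytest.fixture(scope="session")
def table2_spectrum():
    """The printed product-ion m/z values as a unit-intensity peak list."""
    return Spectrum(
        id="table2",
        precursor_mz=857.4914,
        peaks=tuple(Peak(mz, 1.0) for mz, _, _ in TABLE2_ROWS),
    )


@pytest.fixture()
def noiseless_config():
    return SimulationConfig(
        seed=0,
        mass_error_ppm_sigma=0.0,
        intensity_jitter_sigma=0.0,
        noise_peak_mean=0.0,
    )
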