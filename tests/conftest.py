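import numpy as np
import pytest

from trifret import (
    LEICA,
    CascadeGeometry,
    FluorophoreRecord,
    SpectralScene,
    WavelengthGrid,
    synthetic_fluorophores,
)

R0_TRIPLE = (5.7, 5.2, 5.1)


@pytest.fixture(scope="session")
def fluorophores():
    return synthetic_fluorophores()


@pytest.fixture(scope="session")
def donor(fluorophores):
    return fluorophores["mTRQ2"]


@pytest.fixture(scope="session")
def intermediate(fluorophores):
    return fluorophores["mVEN"]


@pytest.fixture(scope="session")
def terminal(fluorophores):
    return fluorophores["mRFP"]


@pytest.fixture
def gaussian_record():
    """Factory for simple Gaussian fluorophores on an arbitrary grid."""

    def make(
        name="gauss",
        em_peak=500.0,
        em_sigma=15.0,
        abs_peak=460.0,
        abs_sigma=15.0,
        eps_max=50000.0,
        quantum_yield=0.8,
        lifetime_ns=3.0,
        grid=WavelengthGrid(300.0, 800.0, 1.0),
    ):
        wl = grid.points()
        em = np.exp(-0.5 * ((wl - em_peak) / em_sigma) ** 2)
        em /= np.trapezoid(em, wl)
        ex = eps_max * np.exp(-0.5 * ((wl - abs_peak) / abs_sigma) ** 2)
        return FluorophoreRecord(
            name=name,
            wavelengths=wl,
            emission=em,
            extinction=ex,
            quantum_yield=quantum_yield,
            lifetime_ns=lifetime_ns,
        )

    return make


@pytest.fixture(scope="session")
def ternary_scene(donor, intermediate, terminal):
    """1:1:1 cascade scene at the 7 nm equidistant arrangement, 458 nm excitation."""
    geom = CascadeGeometry(14.0, 7.0, *R0_TRIPLE)
    return SpectralScene.from_cascade(donor, intermediate, terminal, geom)


@pytest.fixture(scope="session")
def no_fret_scene(donor, intermediate, terminal):
    return SpectralScene(
        members=((donor, 1.0), (intermediate, 1.0), (terminal, 1.0)),
        transfer=np.zeros((3, 3)),
        excitation_nm=458.0,
    )


@pytest.fixture(scope="session")
def leica():
    return LEICA
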