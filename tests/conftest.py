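import numpy as np
import pytest

from flashxtal import builtin_material
from flashxtal.diffraction import AtomSite, ToyCrystal, build_fig7_fixture
from flashxtal.dosimetry import PulseSpec


@pytest.fixture(scope="session")
def avg_protein():
    return builtin_material("avg_protein")


@pytest.fixture(scope="session")
def water():
    return builtin_material("water")


@pytest.fixture(scope="session")
def carbon():
    return builtin_material("carbon")


@pytest.fixture(scope="session")
def pulse_6kev():
    """The reference scenario: 1e12 photons/μm² at 6 keV, 40 fs flat-top."""
    return PulseSpec(energy_ev=6000.0, photons_per_um2=1e12, duration_fs=40.0)


@pytest.fixture(scope="session")
def fig7():
    """(crystal, pulse, motion trajectory, ionization trajectory)."""
    return build_fig7_fixture()


@pytest.fixture(scope="session")
def small_crystal(fig7):
    """3×3×3 version of the toy crystal for Monte-Carlo-scale tests."""
    crystal = fig7[0]
    return ToyCrystal(cell=crystal.cell, motif=crystal.motif, n_cells=(3, 3, 3))


@pytest.fixture(scope="session")
def bravais_crystal():
    """One atom per cell: every pair separation is a lattice vector, so
    finite-box reciprocal-space sums cancel cleanly cell by cell."""
    return ToyCrystal(cell=(25.0, 25.0, 25.0),
                      motif=(AtomSite(position=(0.0, 0.0, 0.0), element="C"),),
                      n_cells=(3, 3, 3))
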