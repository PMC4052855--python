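"""Dose and fluence arithmetic for flat-top femtosecond X-ray pulses.

The central relations, valid for samples much thinner than their absorption
length (single-scattering / thin-sample regime):

* fluence          I₀ = (photons per area) × hν
* dose             D  = I₀ · μ/ρ
* one-photon dose  D₁ = hν · N_A / m_A           (pure element)
* saturation fluence   I₀(sat) = hν / σ_A        (one photon per atom)

Dose rate for a flat-top pulse is simply R = D/T.  A warning is emitted if a
provided sample thickness exceeds a tenth of the absorption length, where the
thin-sample premise starts to bite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from . import materials
from .constants import (
    BARN_TO_CM2,
    EV_TO_J,
    FS_TO_S,
    N_A,
    UM2_TO_CM2,
    UM_PER_CM,
    wavelength_A,
)
from .materials import Composition, CrossSectionTable, get_element

__all__ = [
    "PulseSpec",
    "DoseReport",
    "fluence",
    "dose",
    "dose_rate",
    "dose_to_ev_per_atom",
    "one_photon_dose_pure",
    "saturation_fluence",
    "one_photon_dose_in_matrix",
    "hollow_atom_dose_rate",
    "adiabatic_heating",
    "photons_for_dose",
    "bond_break_dose",
    "make_report",
]


@dataclass(frozen=True)
class PulseSpec:
    """A flat-top X-ray pulse: photon energy, photons per area, duration."""

    energy_ev: float
    photons_per_um2: float
    duration_fs: float
    beam_area_um2: float | None = None

    def __post_init__(self):
        if self.energy_ev <= 0 or self.duration_fs <= 0:
            raise ValueError("photon energy and duration must be positive")
        if self.photons_per_um2 < 0:
            raise ValueError("photons per area must be non-negative")

    @property
    def wavelength_A(self) -> float:
        return wavelength_A(self.energy_ev)

    @property
    def fluence_j_cm2(self) -> float:
        return self.photons_per_um2 / UM2_TO_CM2 * self.energy_ev * EV_TO_J

    @property
    def intensity_w_cm2(self) -> float:
        return self.fluence_j_cm2 / (self.duration_fs * FS_TO_S)

    @property
    def n_photons(self) -> float:
        if self.beam_area_um2 is None:
            raise ValueError("beam area not set")
        return self.photons_per_um2 * self.beam_area_um2


@dataclass(frozen=True)
class DoseReport:
    dose_gy: float
    dose_rate_gy_fs: float
    ev_per_atom: float
    fluence_j_cm2: float
    absorption_length_um: float


def fluence(pulse: PulseSpec) -> float:
    """Pulse fluence I₀ in J/cm²."""
    return pulse.fluence_j_cm2


def dose(pulse: PulseSpec, comp: Composition,
         table: CrossSectionTable | None = None,
         thickness_um: float | None = None) -> float:
    """Absorbed dose in Gy: D = I₀ · μ/ρ, thin-sample model.

    ``thickness_um``, if given, is only used to warn when the sample is no
    longer thin compared with the absorption length.
    """
    mu_over_rho = materials.mass_attenuation(comp, pulse.energy_ev, table)  # cm²/g
    if thickness_um is not None:
        l_abs = materials.absorption_length(comp, pulse.energy_ev, table)
        if thickness_um > 0.1 * l_abs:
            warnings.warn(
                f"sample thickness {thickness_um:g} μm exceeds 10% of the "
                f"absorption length ({l_abs:.0f} μm); thin-sample dose is biased high",
                stacklevel=2,
            )
    return pulse.fluence_j_cm2 * mu_over_rho * 1e3  # (J/cm²)(cm²/g)(g/kg) = J/kg


def dose_rate(pulse: PulseSpec, comp: Composition,
              table: CrossSectionTable | None = None) -> float:
    """Dose rate R = D/T in Gy/fs (flat-top pulse)."""
    return dose(pulse, comp, table) / pulse.duration_fs


def dose_to_ev_per_atom(dose_gy: float, comp: Composition) -> float:
    """Convert a dose to deposited energy per atom, eV."""
    if dose_gy < 0:
        raise ValueError("dose must be non-negative")
    joule_per_atom = dose_gy * comp.mean_atomic_mass * 1e-3 / N_A
    return joule_per_atom / EV_TO_J


def ev_per_atom_to_dose(ev_per_atom: float, comp: Composition) -> float:
    """Inverse of :func:`dose_to_ev_per_atom`."""
    return ev_per_atom * EV_TO_J * N_A / (comp.mean_atomic_mass * 1e-3)


def one_photon_dose_pure(element: str, energy_ev: float) -> float:
    """D₁ = hν·N_A/m_A for a pure element, Gy — no cross-section dependence."""
    if energy_ev <= 0:
        raise ValueError("photon energy must be positive")
    m_kg_mol = get_element(element).m_A * 1e-3
    return energy_ev * EV_TO_J * N_A / m_kg_mol


def saturation_fluence(element: str, energy_ev: float,
                       table: CrossSectionTable | None = None) -> float:
    """Fluence hν/σ_A (J/cm²) at which each atom of the element absorbs
    one photon on average."""
    sigma_cm2 = materials.photoabsorption_cross_section(element, energy_ev, table) * BARN_TO_CM2
    return energy_ev * EV_TO_J / sigma_cm2


def one_photon_dose_in_matrix(element: str, energy_ev: float, comp: Composition,
                              table: CrossSectionTable | None = None) -> float:
    """Dose (Gy) the host matrix receives at the element's saturation fluence."""
    return saturation_fluence(element, energy_ev, table) * \
        materials.mass_attenuation(comp, energy_ev, table) * 1e3


def hollow_atom_dose_rate(element: str, energy_ev: float, comp: Composition,
                          table: CrossSectionTable | None = None) -> float:
    """Dose rate (Gy/fs) needed to ionize the second core electron within the
    K-hole Auger lifetime, producing hollow atoms."""
    tau = get_element(element).tau_auger
    if tau is None:
        raise ValueError(f"no Auger lifetime bundled for {element}")
    return one_photon_dose_in_matrix(element, energy_ev, comp, table) / tau


def adiabatic_heating(dose_gy: float, c_p: float) -> float:
    """Temperature rise ΔT = D/c_p (K) with no heat flow out of the sample."""
    if c_p <= 0:
        raise ValueError("heat capacity must be positive")
    return dose_gy / c_p


def photons_for_dose(dose_gy: float, comp: Composition, energy_ev: float,
                     table: CrossSectionTable | None = None) -> float:
    """Photons per μm² delivering the requested dose; inverse of :func:`dose`."""
    if dose_gy < 0:
        raise ValueError("dose must be non-negative")
    mu_over_rho = materials.mass_attenuation(comp, energy_ev, table)
    fluence_j_cm2 = dose_gy / (mu_over_rho * 1e3)
    return fluence_j_cm2 / (energy_ev * EV_TO_J) * UM2_TO_CM2


def bond_break_dose(bond_energy_ev: float, comp: Composition) -> float:
    """Dose (Gy) corresponding to one bond energy deposited per atom."""
    if bond_energy_ev <= 0:
        raise ValueError("bond energy must be positive")
    return ev_per_atom_to_dose(bond_energy_ev, comp)


def make_report(pulse: PulseSpec, comp: Composition,
                table: CrossSectionTable | None = None) -> DoseReport:
    d = dose(pulse, comp, table)
    return DoseReport(
        dose_gy=d,
        dose_rate_gy_fs=d / pulse.duration_fs,
        ev_per_atom=dose_to_ev_per_atom(d, comp),
        fluence_j_cm2=pulse.fluence_j_cm2,
        absorption_length_um=materials.absorption_length(comp, pulse.energy_ev, table),
    )
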