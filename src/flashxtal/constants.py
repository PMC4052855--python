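"""Physical constants and unit conversions used throughout the package.

Canonical internal units: energies in eV, atomic lengths in Å, attenuation
in cm⁻¹, cross sections in barn, dose in Gy, time in fs, fluence in J/cm².
All conversions funnel through the factors defined here.
"""

# CODATA-2018 values
N_A = 6.02214076e23          # Avogadro constant, 1/mol
EV_TO_J = 1.602176634e-19    # J per eV
M_E_KG = 9.1093837015e-31    # electron mass, kg
R_E_A = 2.8179403262e-5      # classical electron radius, Å
R_E_CM = 2.8179403262e-13    # classical electron radius, cm
EPS0_EV_A = 14.399645        # e²/(4πε₀) in eV·Å (Coulomb energy of two unit charges 1 Å apart)

HC_EV_A = 12398.4            # hc in eV·Å (photon energy × wavelength)

BARN_TO_CM2 = 1e-24
BARN_TO_A2 = 1e-8
A_PER_CM = 1e8
UM_PER_CM = 1e4
UM2_TO_CM2 = 1e-8
FS_TO_S = 1e-15

GY_PER_GGY = 1e9
GY_PER_MGY = 1e6

# heat capacity of water, J kg⁻¹ K⁻¹ — the only built-in (§ adiabatic heating)
C_P_WATER = 4800.0


def wavelength_A(energy_ev: float) -> float:
    """Photon wavelength in Å for a photon energy in eV."""
    if energy_ev <= 0:
        raise ValueError("photon energy must be positive")
    return HC_EV_A / energy_ev
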