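"""Physical constants and unit conversions.

Everything downstream works in angular-frequency units (rad/s).  Magnetic
field strengths and isotropic hyperfine coupling constants are supplied in
millitesla and converted once, with the same gyromagnetic factor
γ = g·μ_B/ħ, so that Zeeman and hyperfine terms are commensurate with the
reaction/relaxation rates (s⁻¹) entering the yield formula.
"""

from scipy.constants import hbar, physical_constants

MU_B = physical_constants["Bohr magneton"][0]  # J/T
HBAR = hbar  # J s

#: Free-electron g-factor; both radical electrons are assumed to carry it.
G_FREE_ELECTRON = 2.00232


def gamma_e(g: float = G_FREE_ELECTRON) -> float:
    """Electron gyromagnetic ratio g·μ_B/ħ in rad s⁻¹ T⁻¹."""
    return g * MU_B / HBAR


def mT_to_angular_frequency(value_mT: float, g: float = G_FREE_ELECTRON) -> float:
    """Convert a field or hyperfine constant from mT to rad/s."""
    return gamma_e(g) * value_mT * 1e-3
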