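"""Physical constants and unit helpers (kcal/mol, Å, K, e)."""

import math

from scipy import constants as _sc

#: Boltzmann constant in kcal/(mol K)
KB_KCAL = _sc.k * _sc.N_A / (_sc.calorie * 1000.0)

#: Coulomb constant in kcal Å / (mol e^2)
COULOMB_KCAL = 332.06

AVOGADRO = _sc.N_A


def kbt(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol at ``temperature`` in K."""
    return KB_KCAL * temperature


def debye_length(ionic_strength: float, temperature: float = 298.0,
                 dielectric: float = 78.4) -> float:
    """Debye screening length in Å.

    Parameters
    ----------
    ionic_strength : molar ionic strength (mol/L) of a 1:1 electrolyte.
    temperature : K.
    dielectric : relative permittivity of the solvent.
    """
    if ionic_strength <= 0:
        return math.inf
    # 2 * NA * e^2 * I  with I in mol/m^3
    denom = 2.0 * _sc.N_A * _sc.e ** 2 * ionic_strength * 1000.0
    lam_m = math.sqrt(dielectric * _sc.epsilon_0 * _sc.k * temperature / denom)
    return lam_m * 1e10
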