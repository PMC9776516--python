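"""Physical constants and unit conversions.

Internal unit system: lengths in Å, charges in protonic units (e),
energies in kT, electrostatic potentials in kT/e, concentrations in
mol/L (M).  The conversion pivot between particle counts and molar
concentrations is ``1 Å³ = 1e-27 L``.
"""

from __future__ import annotations

import numpy as np
from scipy import constants as _sc

#: Avogadro number (1/mol).
N_A: float = _sc.N_A

#: Litres per cubic Ångström.
LITRE_PER_A3: float = 1e-27

#: Molar mass of water (kg/mol), for molality normalisation.
M_WATER: float = 0.018015

#: Particles per Å³ for a 1 M solution.
PER_A3_PER_MOLAR: float = N_A * LITRE_PER_A3


def bjerrum_length(eps_s: float, temperature: float) -> float:
    """Bjerrum length in Å in a medium of relative permittivity *eps_s*.

    The distance at which two unit charges interact with thermal energy kT:
    ``lB = e² / (4π ε0 εs kB T)``.
    """
    lb_vac = _sc.e**2 / (4 * np.pi * _sc.epsilon_0 * _sc.k * temperature)
    return lb_vac * 1e10 / eps_s


def debye_kappa(ionic_strength: float, eps_s: float, temperature: float) -> float:
    """Inverse Debye screening length κ in Å⁻¹.

    ``κ² = 8π lB I N_A`` for a 1:1 salt at ionic strength *I* (M), with the
    number density expressed per Å³.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be non-negative")
    n = ionic_strength * PER_A3_PER_MOLAR
    lb = bjerrum_length(eps_s, temperature)
    return float(np.sqrt(8 * np.pi * lb * n))
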