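"""Physical constants and unit conversions used across the package.

Internal conventions
--------------------
* Atomic structures: ångström (Å), elementary charge (e).
* Colloidal/lattice scale: nanometre (nm), debye (D).
* Energies are computed per particle pair in joule and converted to
  kcal/mol (multiplying by Avogadro's number) or to units of k_B*T only
  at reporting boundaries.

All constants are CODATA 2018 values as shipped with :mod:`scipy.constants`.
"""

from __future__ import annotations

import scipy.constants as _const

#: elementary charge, C
E_CHARGE = _const.e
#: vacuum permittivity, F/m
EPS0 = _const.epsilon_0
#: Boltzmann constant, J/K
K_BOLTZMANN = _const.k
#: Avogadro constant, 1/mol
N_AVOGADRO = _const.N_A

#: 1 debye in C·m
DEBYE = 3.33564e-30
#: 1 e·Å expressed in debye
EA_TO_DEBYE = E_CHARGE * 1e-10 / DEBYE

#: thermochemical calorie, J
CAL = 4.184
#: 1 kcal/mol in J (per particle)
KCAL_PER_MOL = 1e3 * CAL / N_AVOGADRO

ANGSTROM = 1e-10  # m
NM = 1e-9  # m


def joule_to_kcal_per_mol(u_joule: float) -> float:
    """Convert a per-pair energy in J to kcal/mol."""
    return u_joule * N_AVOGADRO / (1e3 * CAL)


def kcal_per_mol_to_kbt(u_kcal: float, temperature: float) -> float:
    """Convert kcal/mol to units of k_B*T at the given temperature (K).

    At 300 K one k_B*T corresponds to 0.59616 kcal/mol.
    """
    kbt_kcal = K_BOLTZMANN * temperature * N_AVOGADRO / (1e3 * CAL)
    return u_kcal / kbt_kcal
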