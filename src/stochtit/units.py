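"""Unit conventions shared across the package.

All protonation free energies are carried in *pK units*: a free energy G is
stored as G / (kB T ln 10), so that a difference of 1 corresponds to one pH
(or pKa) unit at the working temperature.  The Metropolis factor is then
``10**(-dE)`` and Henderson--Hasselbalch behaviour falls out of the isolated
site energies with no further conversion.
"""

import math

import scipy.constants as _const

#: Working temperature (K) used to express Coulomb energies in pK units.
TEMPERATURE_K = 300.0

#: kB*T*ln(10) at the working temperature, in joules.
KT_LN10_J = _const.k * TEMPERATURE_K * math.log(10.0)

#: Coulomb energy of two unit (elementary) charges 1 nm apart in vacuum,
#: expressed in pK units: e^2 / (4 pi eps0 * 1 nm) / (kB T ln10).
#: Numerically ~24.19 pK nm at 300 K.
COULOMB_PK_NM = (
    _const.e**2 / (4.0 * math.pi * _const.epsilon_0 * 1e-9) / KT_LN10_J
)

#: Tolerance (elementary charges) under which a charge sum counts as integer.
#: Matches the 5-6 decimal precision of typical residue-topology files.
INTEGER_CHARGE_TOL = 1e-6
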