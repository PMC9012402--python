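"""Unit system and physical constants.

The engine works in a conventional biomolecular unit system:

=========  =========================
length     angstrom (A)
time       femtosecond (fs)
energy     kcal/mol
mass       atomic mass unit (amu)
charge     elementary charge (e)
angle      radian
=========  =========================

Because kcal/mol, amu, A and fs are not mutually consistent, accelerations
computed as force/mass must be scaled by ``ACCEL_CONV``.  Internally the
dynamics code folds this factor into the masses once (``m_int = m /
ACCEL_CONV``) so that ``a = F / m_int`` is in A/fs^2 and ``0.5 * m_int * v**2``
is in kcal/mol.
"""

# Boltzmann constant, kcal/mol/K
KB = 1.987204e-3

# Coulomb constant, kcal*A/(mol*e^2):  E = COULOMB * q1*q2 / (eps_r * r)
COULOMB = 332.0637

# (A/fs^2) per ((kcal/mol/A) / amu)
ACCEL_CONV = 4.184e-4

# Debye length prefactor, A * sqrt(K^-1 * M):  lambda_D = DEBYE_COEF * sqrt(eps_r*T/I)
# from lambda_D = sqrt(eps0 * eps_r * kB * T / (2 * NA * e^2 * I)) with I in mol/L.
DEBYE_COEF = 0.019885

# default integration time step, fs
DEFAULT_DT = 10.0

# default neighbor-list update interval, steps
DEFAULT_NEIGHBOR_INTERVAL = 20

# default Langevin friction, 1/fs (= 1/ps); a free parameter of the thermostat,
# see docs/methods.md
DEFAULT_FRICTION = 1.0e-3

# Default nonbonded cutoff / pair-list distances (A), keyed by term name.
# exv and go cutoffs are geometric (2*sigma resp. none); pwmcos/hb cutoffs are
# per-site (r0 + 5 A).  Pair-list distances are ~5 A beyond the cutoffs.
DEFAULT_CUTOFF = {
    "ele": 52.0,
    "hps": 39.0,
    "bp": 18.0,
}
DEFAULT_PAIRLIST = {
    "ele": 57.0,
    "hps": 44.0,
    "bp": 23.0,
    "pwmcos": 23.0,
    "hb": 23.0,
    "exv": 15.0,
}

# site/cutoff margin for PWMcos and HB terms (cutoff = r0 + this), A
SITE_CUTOFF_MARGIN = 5.0
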