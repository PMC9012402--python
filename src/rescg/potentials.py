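"""Basic interaction terms: scalar energies and derivatives.

Every function returns ``(E, dE/dx)`` where ``x`` is the scalar internal
coordinate (bond length, angle, dihedral or pair distance).  These are the
reference implementations used by the builder, the brute-force evaluators and
the tests; the simulation engine evaluates the same formulas in compiled
kernels (:mod:`rescg._kernels`).

All energies are in kcal/mol, lengths in A, angles in rad.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .constants import KB, COULOMB, DEBYE_COEF

__all__ = [
    "bond_energy_force",
    "angle_energy_force",
    "dihedral_energy_force",
    "pair_energy_force",
    "permittivity",
    "debye_huckel",
    "modulator",
    "lj_cutoff_ratio",
    "ElectrostaticEnvironment",
    "SplineTable",
]


# ---------------------------------------------------------------------------
# electrostatic environment
# ---------------------------------------------------------------------------

def permittivity(T: float, C: float) -> float:
    """Relative permittivity of aqueous salt solution, eps_r = e(T) * a(C).

    ``e(T)`` is the temperature polynomial for pure water and ``a(C)`` the
    salt-molarity correction; both are empirical fits.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if C < 0:
        raise ValueError("salt molarity must be non-negative")
    e_T = 249.4 - 0.788 * T + 7.20e-4 * T * T
    a_C = 1.0 - 0.2551 * C + 5.151e-2 * C * C - 6.889e-3 * C * C * C
    return e_T * a_C


@dataclass(frozen=True)
class ElectrostaticEnvironment:
    """Solvent state for Debye-Hueckel electrostatics.

    Parameters
    ----------
    temperature : float
        Solution temperature, K.
    salt : float
        Salt molarity, M.  For a 1:1 salt the ionic strength equals the
        molarity, which is the default when ``ionic_strength`` is omitted.
    ionic_strength : float, optional
        Ionic strength, M.

    Attributes
    ----------
    eps_r : float
        Relative permittivity e(T)*a(C).
    debye_length : float
        Debye screening length lambda_D, A.
    """

    temperature: float = 300.0
    salt: float = 0.15
    ionic_strength: float | None = None
    eps_r: float = field(init=False)
    debye_length: float = field(init=False)

    def __post_init__(self):
        I = self.salt if self.ionic_strength is None else self.ionic_strength
        if I <= 0:
            raise ValueError("ionic strength must be positive for screening")
        eps = permittivity(self.temperature, self.salt)
        object.__setattr__(self, "eps_r", eps)
        object.__setattr__(
            self, "debye_length",
            DEBYE_COEF * math.sqrt(eps * self.temperature / I))


def debye_huckel(q1: float, q2: float, r: float,
                 env: ElectrostaticEnvironment) -> tuple[float, float]:
    """Screened Coulomb energy between two point charges (e) at distance r (A)."""
    if r <= 0:
        raise ValueError("r must be positive")
    pref = COULOMB * q1 * q2 / env.eps_r
    s = math.exp(-r / env.debye_length)
    E = pref * s / r
    dE = -E * (1.0 / r + 1.0 / env.debye_length)
    return E, dE


# ---------------------------------------------------------------------------
# bonded terms
# ---------------------------------------------------------------------------

def bond_energy_force(kind: str, params: dict, b: float) -> tuple[float, float]:
    """Bond stretch energy.

    ``kind='harmonic'``: k*(b-b0)^2 with ``params = {k, b0}``.
    ``kind='quartic'``:  k2*(b-b0)^2 + k4*(b-b0)^4 with ``params = {k2, k4, b0}``.
    """
    db = b - params["b0"]
    if kind == "harmonic":
        k = params["k"]
        return k * db * db, 2.0 * k * db
    if kind == "quartic":
        k2, k4 = params["k2"], params["k4"]
        db2 = db * db
        return k2 * db2 + k4 * db2 * db2, 2.0 * k2 * db + 4.0 * k4 * db * db2
    raise ValueError(f"unknown bond kind {kind!r}")


def angle_energy_force(kind: str, params: dict, theta: float) -> tuple[float, float]:
    """Bond-angle energy.

    ``kind='harmonic'``: k*(theta-theta0)^2.
    ``kind='tabulated'``: spline lookup in ``params['table']`` (a
    :class:`SplineTable`); out-of-domain angles clamp to the boundary value.
    """
    if kind == "harmonic":
        d = theta - params["theta0"]
        k = params["k"]
        return k * d * d, 2.0 * k * d
    if kind == "tabulated":
        return params["table"].evaluate(theta)
    raise ValueError(f"unknown angle kind {kind!r}")


def wrap_angle(x: float) -> float:
    """Wrap into (-pi, pi]."""
    y = math.fmod(x + math.pi, 2.0 * math.pi)
    if y <= 0.0:
        y += 2.0 * math.pi
    return y - math.pi


def dihedral_energy_force(kind: str, params: dict, phi: float) -> tuple[float, float]:
    """Torsion energy as a function of the dihedral angle.

    ``kind='periodic'``: sum_n k_n [1 + cos(n (phi - phi0))].
    ``kind='gaussian'``: -eps * exp(-dphi^2 / (2 sigma^2)), dphi wrapped.
    ``kind='tabulated'``: periodic spline lookup.
    """
    if kind == "periodic":
        ns = np.atleast_1d(params["n"])
        ks = np.atleast_1d(params["k"])
        phi0 = params["phi0"]
        E = 0.0
        dE = 0.0
        for n, k in zip(ns, ks):
            E += k * (1.0 + math.cos(n * (phi - phi0)))
            dE += -k * n * math.sin(n * (phi - phi0))
        return E, dE
    if kind == "gaussian":
        d = wrap_angle(phi - params["phi0"])
        s2 = params["sigma"] ** 2
        E = -params["eps"] * math.exp(-d * d / (2.0 * s2))
        return E, -E * d / s2
    if kind == "tabulated":
        return params["table"].evaluate(phi)
    raise ValueError(f"unknown dihedral kind {kind!r}")


# ---------------------------------------------------------------------------
# pair terms
# ---------------------------------------------------------------------------

def _lj(eps: float, sigma: float, r: float) -> tuple[float, float]:
    sr6 = (sigma / r) ** 6
    E = 4.0 * eps * (sr6 * sr6 - sr6)
    dE = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
    return E, dE


def pair_energy_force(kind: str, params: dict, r: float) -> tuple[float, float]:
    """Pairwise nonbonded energy as a function of distance.

    Supported kinds and their parameters:

    - ``go1210``: native-contact 12-10 well, ``{eps, sigma}``; minimum -eps at
      r = sigma.
    - ``lj126``: 12-6 Lennard-Jones, ``{eps, sigma}``.
    - ``exv_lj_trunc``: LJ truncated and shifted at its minimum (purely
      repulsive), ``{eps, sigma}``; zero for r >= sigma.
    - ``exv12``: 1/r^12 excluded volume with shift -2^-12 eps, ``{eps, sigma}``;
      zero for r >= 2 sigma.
    - ``gaussian``: -eps * exp(-(r-r0)^2 / 2 w^2), ``{eps, r0, w}``.
    - ``morse``, ``morse_rep``, ``morse_attr``: Morse well and its
      repulsive/attractive split, ``{eps, alpha, r0}``.
    - ``ashbaugh_hatch``: hydropathy-scaled LJ, ``{eps, sigma, lam}``.
    """
    if kind == "go1210":
        eps, sigma = params["eps"], params["sigma"]
        sr = sigma / r
        sr10 = sr ** 10
        sr12 = sr10 * sr * sr
        E = eps * (5.0 * sr12 - 6.0 * sr10)
        dE = eps * (-60.0 * sr12 + 60.0 * sr10) / r
        return E, dE
    if kind == "lj126":
        return _lj(params["eps"], params["sigma"], r)
    if kind == "exv_lj_trunc":
        eps, sigma = params["eps"], params["sigma"]
        if r >= sigma:
            return 0.0, 0.0
        sr6 = (sigma / r) ** 6
        E = eps * (sr6 * sr6 - 2.0 * sr6) + eps
        dE = eps * (-12.0 * sr6 * sr6 + 12.0 * sr6) / r
        return E, dE
    if kind == "exv12":
        eps, sigma = params["eps"], params["sigma"]
        if r >= 2.0 * sigma:
            return 0.0, 0.0
        sr12 = (sigma / r) ** 12
        return eps * sr12 - eps * 2.0 ** -12, -12.0 * eps * sr12 / r
    if kind == "gaussian":
        eps, r0, w = params["eps"], params["r0"], params["w"]
        d = r - r0
        E = -eps * math.exp(-d * d / (2.0 * w * w))
        return E, -E * d / (w * w)
    if kind in ("morse", "morse_rep", "morse_attr"):
        eps, alpha, r0 = params["eps"], params["alpha"], params["r0"]
        u = math.exp(-alpha * (r - r0))
        E_full = eps * (1.0 - u) ** 2 - eps
        dE_full = 2.0 * eps * alpha * u * (1.0 - u)
        if kind == "morse":
            return E_full, dE_full
        if kind == "morse_rep":
            if r >= r0:
                return 0.0, 0.0
            return E_full + eps, dE_full
        # morse_attr
        if r < r0:
            return -eps, 0.0
        return E_full, dE_full
    if kind == "ashbaugh_hatch":
        eps, sigma, lam = params["eps"], params["sigma"], params["lam"]
        E_lj, dE_lj = _lj(eps, sigma, r)
        if r <= 2.0 ** (1.0 / 6.0) * sigma:
            return E_lj + (1.0 - lam) * eps, dE_lj
        return lam * E_lj, lam * dE_lj
    raise ValueError(f"unknown pair kind {kind!r}")


def modulator(dtheta: float, gamma: float) -> tuple[float, float]:
    """Angle-gating function f(dtheta) in [0, 1] and its derivative.

    f = 1 for |dtheta| < gamma, decays as 1 - cos^2(pi*dtheta/(2*gamma)) on
    gamma <= |dtheta| <= 2*gamma and is 0 beyond; C1 at both joins.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    a = abs(dtheta)
    if a < gamma:
        return 1.0, 0.0
    if a >= 2.0 * gamma:
        return 0.0, 0.0
    c = math.cos(math.pi * dtheta / (2.0 * gamma))
    f = 1.0 - c * c
    df = (math.pi / (2.0 * gamma)) * math.sin(math.pi * dtheta / gamma)
    return f, df


def lj_cutoff_ratio(tolerance: float = 1e-4) -> float:
    """r/sigma at which |E_LJ| falls to ``tolerance`` * eps (largest root).

    Beyond the minimum the 12-6 energy is negative and monotonically rises to
    zero, so |E| = tolerance*eps has exactly one root past the point where
    |E| = eps would sit; it is bracketed and polished with Brent's method.
    For tolerance 1e-4 the ratio is ~5.849.
    """
    if not 0.0 < tolerance < 1.0:
        raise ValueError("tolerance must be in (0, 1)")

    def g(x):  # |E_LJ(x*sigma)|/eps - tolerance on the attractive tail
        x6 = x ** -6
        return abs(4.0 * (x6 * x6 - x6)) - tolerance

    lo = 2.0 ** (1.0 / 6.0)  # minimum, |E| = eps there
    hi = 2.0 * lo
    while g(hi) > 0.0:
        hi *= 2.0
    return brentq(g, lo, hi, xtol=1e-9)


# ---------------------------------------------------------------------------
# tabulated (statistical) local terms
# ---------------------------------------------------------------------------

class SplineTable:
    """C1 cubic-spline interpolant of a tabulated local potential.

    Used for the knowledge-based (Boltzmann-inversion) angle and dihedral
    terms, whose numeric content ships as parameter data.  The grid must be
    uniform; dihedral tables are closed periodically, angle tables use a
    not-a-knot cubic (exact for polynomial tables up to cubic order) and
    clamp out-of-domain queries to the boundary value (recorded in
    :attr:`clamp_count` rather than raising mid-run).
    """

    def __init__(self, grid: np.ndarray, energies: np.ndarray,
                 periodic: bool = False):
        grid = np.asarray(grid, dtype=float)
        energies = np.asarray(energies, dtype=float)
        steps = np.diff(grid)
        if grid.ndim != 1 or grid.size < 4:
            raise ValueError("need a 1-D grid with at least 4 points")
        if not np.allclose(steps, steps[0]):
            raise ValueError("grid must be uniform")
        if periodic and not math.isclose(energies[0], energies[-1],
                                         abs_tol=1e-9):
            energies = energies.copy()
            energies[-1] = energies[0]
        self.grid = grid
        self.energies = energies
        self.periodic = periodic
        self.clamp_count = 0
        bc = "periodic" if periodic else "not-a-knot"
        self._spline = CubicSpline(grid, energies, bc_type=bc)
        self._dspline = self._spline.derivative()

    @classmethod
    def from_boltzmann(cls, grid, probabilities, temperature,
                       periodic=False, sin_correct=False):
        """Build -kB*T*ln P(x) (optionally /sin x for angles) from a histogram."""
        p = np.asarray(probabilities, dtype=float)
        if np.any(p <= 0):
            raise ValueError("probabilities must be strictly positive")
        g = np.asarray(grid, dtype=float)
        if sin_correct:
            p = p / np.sin(g)
        return cls(g, -KB * temperature * np.log(p), periodic=periodic)

    def evaluate(self, x: float) -> tuple[float, float]:
        if self.periodic:
            span = self.grid[-1] - self.grid[0]
            x = self.grid[0] + (x - self.grid[0]) % span
        elif x < self.grid[0]:
            self.clamp_count += 1
            return float(self.energies[0]), 0.0
        elif x > self.grid[-1]:
            self.clamp_count += 1
            return float(self.energies[-1]), 0.0
        return float(self._spline(x)), float(self._dspline(x))

    def coefficients(self):
        """(breakpoints, 4 x nseg coefficient array) for the compiled kernels."""
        return self._spline.x, self._spline.c
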