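"""Scalar interaction terms: printed-formula values, derivative consistency
and the electrostatic environment."""

import math
import time

import numpy as np
import pytest

from rescg.potentials import (ElectrostaticEnvironment, SplineTable,
                              angle_energy_force, bond_energy_force,
                              debye_huckel, dihedral_energy_force,
                              lj_cutoff_ratio, modulator, pair_energy_force,
                              permittivity)


# ---------------------------------------------------------------------------
# fixed values forced by the formulas
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kind,params,x,e_exp,d_exp", [
    ("harmonic", {"k": 100.0, "b0": 3.8}, 3.8, 0.0, 0.0),
    ("harmonic", {"k": 100.0, "b0": 3.8}, 3.9, 1.0, 20.0),
    ("quartic", {"k2": 1.0, "k4": 1.0, "b0": 3.0}, 4.0, 2.0, 6.0),
])
def test_bond_values(kind, params, x, e_exp, d_exp):
    e, d = bond_energy_force(kind, params, x)
    assert e == pytest.approx(e_exp, abs=1e-12)
    assert d == pytest.approx(d_exp, abs=1e-12)


def test_angle_harmonic():
    e, _ = angle_energy_force("harmonic", {"k": 20.0, "theta0": 1.8}, 1.9)
    assert e == pytest.approx(0.2, abs=1e-12)


def test_dihedral_values():
    e, d = dihedral_energy_force("periodic",
                                 {"k": 1.0, "n": 1, "phi0": 0.7}, 0.7)
    assert e == pytest.approx(2.0)      # k [1 + cos 0]
    e0, _ = dihedral_energy_force("gaussian",
                                  {"eps": 2.0, "sigma": 0.3, "phi0": 0.5},
                                  0.5)
    assert e0 == pytest.approx(-2.0)
    e1, _ = dihedral_energy_force("gaussian",
                                  {"eps": 2.0, "sigma": 0.3, "phi0": 0.5},
                                  0.8)
    assert e1 == pytest.approx(-2.0 * math.exp(-0.5))


def test_dihedral_gaussian_wraps():
    params = {"eps": 1.5, "sigma": 0.4, "phi0": 0.0}
    e_a, _ = dihedral_energy_force("gaussian", params, math.pi + 0.1 - 2 * math.pi)
    e_b, _ = dihedral_energy_force("gaussian", params, -(math.pi - 0.1))
    assert e_a == pytest.approx(e_b, rel=1e-12)


def test_go_contact_minimum_and_shape():
    e, d = pair_energy_force("go1210", {"eps": 1.7, "sigma": 4.0}, 4.0)
    assert e == pytest.approx(-1.7)
    assert d == pytest.approx(0.0, abs=1e-12)
    # direct evaluation of the 12-10 form at r = 1.2 sigma
    e, _ = pair_energy_force("go1210", {"eps": 1.0, "sigma": 1.0}, 1.2)
    assert e == pytest.approx(5 * 1.2 ** -12 - 6 * 1.2 ** -10, rel=1e-12)
    assert e == pytest.approx(-0.40825, abs=1e-4)


def test_exv12_shift_and_cutoff():
    p = {"eps": 1.0, "sigma": 2.0}
    assert pair_energy_force("exv12", p, 4.0)[0] == 0.0
    assert pair_energy_force("exv12", p, 5.0)[0] == 0.0
    e, _ = pair_energy_force("exv12", p, 2.0)
    assert e == pytest.approx(1.0 - 2.0 ** -12)


def test_exv_lj_trunc_joins_continuously():
    p = {"eps": 0.5, "sigma": 3.0}
    e_in, d_in = pair_energy_force("exv_lj_trunc", p, 3.0 - 1e-9)
    assert pair_energy_force("exv_lj_trunc", p, 3.0)[0] == 0.0
    assert e_in == pytest.approx(0.0, abs=1e-8)
    assert d_in == pytest.approx(0.0, abs=1e-6)


def test_morse_split_at_minimum():
    p = {"eps": 3.0, "alpha": 2.0, "r0": 4.0}
    assert pair_energy_force("morse_rep", p, 4.0)[0] == 0.0
    assert pair_energy_force("morse_attr", p, 4.0)[0] == pytest.approx(-3.0)
    assert pair_energy_force("morse_attr", p, 3.0)[0] == pytest.approx(-3.0)
    assert pair_energy_force("morse_attr", p, 3.0)[1] == 0.0
    assert pair_energy_force("morse_rep", p, 5.0)[0] == 0.0


def test_ashbaugh_hatch_continuous_at_switch():
    p = {"eps": 0.2, "sigma": 6.0, "lam": 0.5}
    r_sw = 2.0 ** (1 / 6) * 6.0
    below = pair_energy_force("ashbaugh_hatch", p, r_sw - 1e-8)[0]
    above = pair_energy_force("ashbaugh_hatch", p, r_sw + 1e-8)[0]
    assert below == pytest.approx(above, abs=1e-6)
    # lam = 1 reduces to plain LJ
    p1 = {"eps": 0.2, "sigma": 6.0, "lam": 1.0}
    for r in (5.0, 7.0, 9.0):
        e_ah, _ = pair_energy_force("ashbaugh_hatch", p1, r)
        e_lj, _ = pair_energy_force("lj126", {"eps": 0.2, "sigma": 6.0}, r)
        assert e_ah == pytest.approx(e_lj, rel=1e-12)


def test_modulator_values_and_gates():
    g = 0.3
    assert modulator(0.0, g) == (1.0, 0.0)
    assert modulator(2 * g, g)[0] == 0.0
    assert modulator(5 * g, g)[0] == 0.0
    f, _ = modulator(1.5 * g, g)
    assert f == pytest.approx(0.5)
    # C1 joins
    for x in (g, 2 * g):
        f_lo, d_lo = modulator(x - 1e-9, g)
        f_hi, d_hi = modulator(x + 1e-9, g)
        assert f_lo == pytest.approx(f_hi, abs=1e-7)
        assert d_lo == pytest.approx(d_hi, abs=1e-6)


# ---------------------------------------------------------------------------
# derivative consistency (central differences)
# ---------------------------------------------------------------------------

_CASES = [
    ("bond", "harmonic", {"k": 55.0, "b0": 3.8}, 4.1),
    ("bond", "quartic", {"k2": 0.6, "k4": 600.0, "b0": 4.6}, 4.8),
    ("angle", "harmonic", {"k": 20.0, "theta0": 1.8}, 2.1),
    ("dihedral", "periodic", {"k": 1.5, "n": 3, "phi0": 0.4}, 1.1),
    ("dihedral", "gaussian", {"eps": 1.2, "sigma": 0.25, "phi0": -0.6}, -0.2),
    ("pair", "go1210", {"eps": 0.8, "sigma": 5.5}, 6.3),
    ("pair", "lj126", {"eps": 0.2, "sigma": 6.0}, 7.7),
    ("pair", "exv12", {"eps": 0.2, "sigma": 2.2}, 3.1),
    ("pair", "exv_lj_trunc", {"eps": 0.3, "sigma": 4.4}, 3.9),
    ("pair", "gaussian", {"eps": 1.0, "r0": 6.0, "w": 1.2}, 6.9),
    ("pair", "morse", {"eps": 3.0, "alpha": 2.5, "r0": 4.1}, 4.6),
    ("pair", "morse_rep", {"eps": 3.0, "alpha": 2.5, "r0": 4.1}, 3.7),
    ("pair", "morse_attr", {"eps": 3.0, "alpha": 2.5, "r0": 4.1}, 4.9),
    ("pair", "ashbaugh_hatch", {"eps": 0.2, "sigma": 6.0, "lam": 0.6}, 6.1),
]


@pytest.mark.parametrize("family,kind,params,x", _CASES)
def test_analytic_derivative_matches_central_difference(family, kind,
                                                        params, x):
    fn = {"bond": bond_energy_force, "angle": angle_energy_force,
          "dihedral": dihedral_energy_force,
          "pair": pair_energy_force}[family]
    h = 1e-5 * max(abs(x), 1.0)
    e_p, _ = fn(kind, params, x + h)
    e_m, _ = fn(kind, params, x - h)
    _, d = fn(kind, params, x)
    fd = (e_p - e_m) / (2 * h)
    assert d == pytest.approx(fd, rel=1e-4, abs=1e-8)


# ---------------------------------------------------------------------------
# electrostatic environment
# ---------------------------------------------------------------------------

def test_permittivity_polynomials():
    assert permittivity(300.0, 0.0) == pytest.approx(77.8, abs=1e-9)
    a15 = 1 - 0.2551 * 0.15 + 5.151e-2 * 0.15 ** 2 - 6.889e-3 * 0.15 ** 3
    assert permittivity(300.0, 0.15) == pytest.approx(77.8 * a15, rel=1e-12)


def test_debye_length_square_root_scaling():
    e1 = ElectrostaticEnvironment(300.0, 0.1, ionic_strength=0.1)
    e4 = ElectrostaticEnvironment(300.0, 0.1, ionic_strength=0.4)
    assert e4.debye_length == pytest.approx(e1.debye_length / 2, rel=1e-12)
    # monotone decrease in I
    prev = np.inf
    for I in (0.05, 0.1, 0.2, 0.5, 1.0):
        lam = ElectrostaticEnvironment(300.0, 0.15, ionic_strength=I
                                       ).debye_length
        assert lam < prev
        prev = lam


def test_debye_huckel_functional_form():
    env = ElectrostaticEnvironment(300.0, 0.15)
    assert debye_huckel(0.0, 1.0, 10.0, env)[0] == 0.0
    lam = env.debye_length
    for r in (5.0, 20.0, 45.0):
        e_r = debye_huckel(1, 1, r, env)[0]
        e_rl = debye_huckel(1, 1, r + lam, env)[0]
        assert e_rl / e_r == pytest.approx(math.exp(-1) * r / (r + lam),
                                           rel=1e-10)


def test_electrostatic_cutoff_bound():
    env = ElectrostaticEnvironment(300.0, 0.15)
    e, _ = debye_huckel(1.0, 1.0, 52.0, env)
    assert abs(e) <= 1e-4


# ---------------------------------------------------------------------------
# LJ cutoff ratio
# ---------------------------------------------------------------------------

def test_lj_cutoff_ratio_printed_value():
    t0 = time.time()
    ratio = lj_cutoff_ratio(1e-4)
    assert time.time() - t0 < 1.0
    assert ratio == pytest.approx(5.849, abs=1e-3)


def test_lj_cutoff_ratio_against_grid_scan():
    ratio = lj_cutoff_ratio(1e-4)
    # dense-grid oracle: largest x where |E| crosses the tolerance
    x = np.linspace(2.0 ** (1 / 6), 12.0, 2_000_001)
    e = np.abs(4.0 * (x ** -12.0 - x ** -6.0))
    above = np.where(e >= 1e-4)[0]
    bracket = (x[above[-1]], x[above[-1] + 1])
    assert bracket[0] <= ratio <= bracket[1]
    assert ratio == pytest.approx(bracket[0], abs=1e-5)


def test_lj_unit_tolerance_root_is_wca_distance():
    # |E| = eps has its largest root at the minimum position 2^(1/6) sigma
    assert lj_cutoff_ratio(1.0 - 1e-12) == pytest.approx(2 ** (1 / 6),
                                                         abs=1e-6)


# ---------------------------------------------------------------------------
# spline tables
# ---------------------------------------------------------------------------

def test_spline_reproduces_closed_form():
    grid = np.radians(np.arange(40.0, 171.0, 1.0))
    k, th0 = 8.0, math.radians(100.0)
    tab = SplineTable(grid, k * (grid - th0) ** 2)
    xs = np.linspace(grid[0], grid[-1], 500)
    for x in xs:
        e, d = tab.evaluate(float(x))
        assert e == pytest.approx(k * (x - th0) ** 2, abs=1e-4)
    # exact at the nodes, zero slope at the symmetric minimum
    for g, v in zip(grid, k * (grid - th0) ** 2):
        assert tab.evaluate(float(g))[0] == pytest.approx(v, abs=1e-12)
    assert tab.evaluate(th0)[1] == pytest.approx(0.0, abs=1e-3)


def test_spline_clamps_out_of_domain():
    grid = np.linspace(1.0, 2.0, 11)
    tab = SplineTable(grid, np.ones(11))
    e, d = tab.evaluate(0.5)
    assert (e, d) == (1.0, 0.0)
    assert tab.clamp_count == 1


# ---------------------------------------------------------------------------
# randomized invariants
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.floats(-10.0, 10.0), st.floats(0.05, 2.0))
def test_modulator_bounded_everywhere(dtheta, gamma):
    f, _ = modulator(dtheta, gamma)
    assert 0.0 <= f <= 1.0


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.floats(0.3, 30.0), st.floats(0.5, 8.0), st.floats(0.01, 5.0))
def test_excluded_volume_never_negative(r, sigma, eps):
    for kind in ("exv12", "exv_lj_trunc"):
        e, _ = pair_energy_force(kind, {"eps": eps, "sigma": sigma}, r)
        assert e >= -1e-12


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.floats(0.5, 20.0), st.floats(0.2, 5.0), st.floats(0.1, 4.0),
       st.floats(1.0, 10.0))
def test_gaussian_and_morse_attraction_never_positive(r, eps, alpha, r0):
    e_g, _ = pair_energy_force("gaussian", {"eps": eps, "r0": r0, "w": 1.0},
                               r)
    assert e_g <= 1e-12
    e_m, _ = pair_energy_force("morse_attr",
                               {"eps": eps, "alpha": alpha, "r0": r0}, r)
    assert e_m <= 1e-12
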