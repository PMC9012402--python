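"""Assembled model energy functions: exclusions, native-structure minima,
invariances, gating identities, force-energy consistency, and the
model-combination matrix."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rescg import builder, models
from rescg.io.pwm import PWM
from rescg.models import CGSystem, CombinationError, build_exclusions, \
    pwm_to_epsilon
from rescg.parameters import flexible_tables
from rescg.topology import (Bonds, CGTopology, Dihedrals, Frame)
from conftest import bare_particles


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

def test_linear_chain_exclusions():
    P = bare_particles(4)
    top = CGTopology(
        particles=P,
        bonds=Bonds(np.array([[0, 1], [1, 2], [2, 3]]), np.ones(3, np.int64),
                    np.full(3, 3.8), np.ones(3), np.zeros(3)),
        dihedrals=Dihedrals(np.array([[0, 1, 2, 3]]), np.array([1]),
                            np.zeros(1), np.ones(1, np.int64), np.ones(1),
                            np.zeros(1), np.array([""], dtype=object)))
    excl = build_exclusions(top)
    assert excl.nonbonded == {(0, 1), (1, 2), (2, 3), (0, 2), (1, 3), (0, 3)}


def test_contacts_excluded_from_exv_only(helix_system):
    top, frame, system = helix_system
    excl = build_exclusions(top)
    for i, j in top.contacts.idx:
        pair = (min(i, j), max(i, j))
        assert pair in excl.exv
        assert pair not in excl.nonbonded


def test_wc_partners_excluded_from_exv(dna_system):
    top, frame, system = dna_system
    excl = build_exclusions(top)
    for i, j in top.extra_exclusions:
        assert (min(i, j), max(i, j)) in excl.exv
    # but they remain base-pair candidates
    lists = system.build_neighbor_lists(frame.positions)
    bp_pairs = {tuple(p) for p in lists.pairs["bp"]}
    for i, j in top.extra_exclusions:
        assert (min(i, j), max(i, j)) in bp_pairs


# ---------------------------------------------------------------------------
# native-structure minima and invariances
# ---------------------------------------------------------------------------

def test_aicg2p_native_minimum(helix_system):
    top, frame, system = helix_system
    rep = system.energy_forces(frame)
    assert rep["bond"] == pytest.approx(0.0, abs=1e-20)
    assert rep["contact_go"] == pytest.approx(-np.sum(top.contacts.eps))
    assert rep["gauss13"] == pytest.approx(-np.sum(top.gauss13.eps))


def test_two_residue_contact_at_12_sigma():
    P = bare_particles(2, chain=["A", "B"])
    top = CGTopology(particles=P)
    top.contacts.idx = np.array([[0, 1]])
    top.contacts.sigma = np.array([5.0])
    top.contacts.eps = np.array([1.0])
    system = CGSystem(top)
    rep = system.energy_forces(np.array([[0.0, 0, 0], [6.0, 0, 0]]))
    assert rep["contact_go"] == pytest.approx(5 * 1.2 ** -12 - 6 * 1.2 ** -10,
                                              rel=1e-12)


def test_rigid_motion_invariance(helix_system):
    top, frame, system = helix_system
    e0 = system.energy_forces(frame).total
    shifted = frame.positions + np.array([10.0, 10.0, 10.0])
    assert system.energy_forces(shifted).total == pytest.approx(e0, rel=1e-12)
    rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
    rotated = frame.positions @ rot.T + 5.0
    assert system.energy_forces(rotated).total == pytest.approx(e0, rel=1e-10)


def test_rna_native_minimum_and_intra_ele_flag(duplex):
    # build an "RNA" from the duplex geometry: remap classes
    cg = duplex.cgmap
    rna = builder.CGMap(
        name=np.array([n.replace("D", "R") for n in cg.name], dtype=object),
        mol_class=np.array(["rna"] * len(cg), dtype=object),
        residue=np.array([("U" if b == "T" else str(b)) for b in cg.residue],
                         dtype=object),
        chain=cg.chain.copy(), resid=cg.resid.copy(), mass=cg.mass.copy(),
        positions=cg.positions.copy(), groups=cg.groups, source=cg.source)
    top, frame = builder.generate_model_topology(rna, "rna_struct")
    builder.assign_charges(top, "integer")
    sys_off = CGSystem(top, options={"intra_rna_ele": False})
    sys_on = CGSystem(top, options={"intra_rna_ele": True})
    rep_off = sys_off.energy_forces(frame)
    rep_on = sys_on.energy_forces(frame)
    assert rep_off["bond"] == pytest.approx(0.0, abs=1e-18)
    assert rep_off["angle"] == pytest.approx(0.0, abs=1e-18)
    assert rep_off["contact_go"] == pytest.approx(-np.sum(top.contacts.eps))
    assert "ele" not in rep_off.terms
    assert rep_on["ele"] != 0.0


def test_hps_reduces_to_lj_when_lambda_one():
    cg = builder.make_fixture("idp_chain", n=8, seed=1)
    top, frame = builder.generate_model_topology(cg, "hps")
    top.particles.lam[:] = 1.0
    system = CGSystem(top)
    rep = system.energy_forces(frame, brute=True)
    # independent plain-LJ sum over the same pairs
    from rescg.potentials import pair_energy_force
    e_lj = 0.0
    excl = build_exclusions(top).nonbonded
    pos = frame.positions
    for i in range(8):
        for j in range(i + 1, 8):
            if (i, j) in excl:
                continue
            r = np.linalg.norm(pos[i] - pos[j])
            if r < 39.0:
                s = 0.5 * (top.particles.sigma[i] + top.particles.sigma[j])
                e_lj += pair_energy_force("lj126", {"eps": 0.2, "sigma": s},
                                          r)[0]
    assert rep["hps"] == pytest.approx(e_lj, rel=1e-10)


def test_hps_zero_lambda_beyond_core_is_zero():
    P = bare_particles(2, chain=["A", "B"])
    P.sigma[:] = 6.0
    P.lam[:] = 0.0
    P.eps[:] = 0.2
    top = CGTopology(particles=P)
    system = CGSystem(top)
    r = 2 ** (1 / 6) * 6.0 + 1.0
    rep = system.energy_forces(np.array([[0.0, 0, 0], [r, 0, 0]]),
                               brute=True)
    assert rep.terms.get("hps", 0.0) == pytest.approx(0.0, abs=1e-14)


# ---------------------------------------------------------------------------
# brute-force vs neighbor-list equality
# ---------------------------------------------------------------------------

def test_two_chain_hps_list_equals_double_loop():
    cg = builder.make_fixture("idp_chain", n=5, count=2, seed=6)
    top, frame = builder.generate_model_topology(cg, "hps")
    builder.assign_charges(top, "integer")
    system = CGSystem(top)
    r_list = system.energy_forces(frame)
    r_brute = system.energy_forces(frame, brute=True)
    for k in set(r_list.terms) | set(r_brute.terms):
        assert r_list.terms.get(k, 0.0) == pytest.approx(
            r_brute.terms.get(k, 0.0), rel=1e-10, abs=1e-12)
    assert np.allclose(r_list.forces, r_brute.forces, atol=1e-10)


def test_complex_list_equals_brute(protein_dna_complex):
    top, frame = protein_dna_complex
    pwm = PWM(scores=np.linspace(-1, 1, 40).reshape(4, 10),
              n_contacts=np.full(10, 2.0))
    system = CGSystem(top, pwm=pwm, pwm_gamma=1.2, pwm_shift=0.3,
                      tables=flexible_tables())
    r_list = system.energy_forces(frame)
    r_brute = system.energy_forces(frame, brute=True)
    for k in set(r_list.terms) | set(r_brute.terms):
        assert r_list.terms.get(k, 0.0) == pytest.approx(
            r_brute.terms.get(k, 0.0), rel=1e-10, abs=1e-12)


# ---------------------------------------------------------------------------
# force-energy consistency on a mixed fixture
# ---------------------------------------------------------------------------

def test_forces_match_finite_differences_mixed(protein_dna_complex):
    top, frame = protein_dna_complex
    pwm = PWM(scores=np.linspace(-2, 1, 40).reshape(4, 10),
              n_contacts=np.full(10, 2.0))
    system = CGSystem(top, pwm=pwm, pwm_gamma=1.5, pwm_shift=0.2,
                      tables=flexible_tables())
    rng = np.random.default_rng(0)
    pos = frame.positions + 0.12 * rng.standard_normal(frame.positions.shape)
    rep = system.energy_forces(pos, brute=True)
    h = 1e-5
    for i, a in [(0, 0), (3, 1), (11, 2), (12, 0), (20, 1), (40, 2),
                 (len(pos) - 1, 0)]:
        p1 = pos.copy()
        p1[i, a] += h
        p2 = pos.copy()
        p2[i, a] -= h
        fd = -(system.energy_forces(p1, brute=True).total
               - system.energy_forces(p2, brute=True).total) / (2 * h)
        assert rep.forces[i, a] == pytest.approx(
            fd, rel=1e-4, abs=1e-6), (i, a)


def test_newton_third_law_and_torque(helix_system):
    top, frame, system = helix_system
    rng = np.random.default_rng(2)
    pos = frame.positions + 0.2 * rng.standard_normal(frame.positions.shape)
    rep = system.energy_forces(pos)
    assert np.abs(rep.forces.sum(axis=0)).max() < 1e-8
    torque = np.cross(pos, rep.forces).sum(axis=0)
    assert np.abs(torque).max() < 1e-6
    assert rep.total == pytest.approx(sum(rep.terms.values()), rel=1e-10)


# ---------------------------------------------------------------------------
# protein-DNA site terms: reference values and gating
# ---------------------------------------------------------------------------

def test_pwm_to_epsilon_map():
    pwm = PWM(scores=np.full((4, 6), -2.0), n_contacts=np.full(6, 4.0))
    # uniform column -> identical eps for every base
    vals = {b: pwm_to_epsilon(pwm, 2, b, gamma=2.0, eps_shift=0.5)
            for b in "ACGT"}
    assert len({round(v, 12) for v in vals.values()}) == 1
    # gamma = 0 kills the term
    assert pwm_to_epsilon(pwm, 0, "A", gamma=0.0, eps_shift=9.9) == 0.0
    # e=-2, N=4, eps'=0.5, gamma=2 -> 2 * (-0.5 + 0.5) = 0
    assert vals["A"] == pytest.approx(0.0, abs=1e-12)


def test_pwmcos_reference_energy_and_gates(protein_dna_complex):
    top, frame = protein_dna_complex
    pwm = PWM(scores=np.full((4, 10), 4.0), n_contacts=np.full(10, 2.0))
    system = CGSystem(top, pwm=pwm, pwm_gamma=1.0, pwm_shift=0.0,
                      tables=flexible_tables())
    # native geometry: every (site, its own base) term sits at its Gaussian
    # peak with all modulators = 1, so each contributes exactly -eps
    lists = system.brute_force_lists(frame.positions)
    site_base, eps = lists.pairs["pwmcos"]
    rep = system.energy_forces(frame, lists=lists)
    native = 0.0
    pos = frame.positions
    pw = top.pwmcos
    for (s, b), e in zip(site_base, eps):
        r = np.linalg.norm(pos[pw.ca_idx[s]] - pos[b])
        if abs(r - pw.r0[s]) < 1e-9:
            native += -e
    # the native contributions dominate; off-site bases add the remainder
    assert rep["pwmcos"] <= native + 1e-9
    assert native < 0.0


def test_hb_reference_and_modulator_arithmetic(protein_dna_complex):
    import copy
    top, frame = protein_dna_complex
    top = copy.deepcopy(top)
    top.pwmcos = None
    system = CGSystem(top, tables=flexible_tables())
    rep = system.energy_forces(frame)
    # at the native geometry every HB site contributes exactly -eps
    assert rep["hb"] == pytest.approx(-np.sum(top.hbsites.eps), rel=1e-9)
    # HB is independent of phosphate charge
    top.particles.charge[:] = 0.0
    rep2 = CGSystem(top, tables=flexible_tables()).energy_forces(frame)
    assert rep2["hb"] == pytest.approx(rep["hb"], rel=1e-12)


def test_hb_half_modulator():
    """E = -eps/2 at r = r0 when one gating angle sits at 1.5 gamma."""
    from rescg import _kernels as K
    box = np.ones(3)
    gamma = 0.2
    th1_ref = 2.0
    # geometry: S - P - Ca colinear arms in the xy-plane
    p = np.array([0.0, 0.0, 0.0])
    ca = np.array([6.0, 0.0, 0.0])
    th1 = th1_ref + 1.5 * gamma
    s = p + 4.0 * np.array([np.cos(th1), np.sin(th1), 0.0])
    ca_prev = ca + np.array([-1.0, -3.8, 0.0])
    ca_next = ca + np.array([1.0, 3.8, 0.0])
    pos = np.array([s, p, ca, ca_prev, ca_next])
    v = pos[4] - pos[3]
    u = ca - p
    th2_ref = float(np.arccos(v @ u / (np.linalg.norm(v)
                                       * np.linalg.norm(u))))
    F = np.zeros_like(pos)
    e = K.hb_sites_ef(
        pos, np.array([1]), np.array([0]), np.array([2]), np.array([3]),
        np.array([4]), np.array([6.0]), np.array([th1_ref]),
        np.array([th2_ref]), np.array([2.0]), np.array([1.0]),
        np.array([gamma]), box, False, F)
    assert e == pytest.approx(-1.0, rel=1e-12)   # -eps * 0.5 * 1


def test_site_gating_zeroes_attraction():
    """Base pairing at its reference geometry gives -eps per pair; pushing
    one gating angle past 2*gamma leaves only the (zero-at-r0) repulsion."""
    from rescg import _kernels as K
    box = np.ones(3)
    gamma = 0.13
    r0, th1, th2 = 5.6, 2.0, 1.9
    b1 = np.zeros(3)
    b2 = np.array([r0, 0.0, 0.0])
    s1 = b1 + 4.0 * np.array([np.cos(th1), np.sin(th1), 0.0])
    s2 = b2 + 4.0 * np.array([-np.cos(th2), np.sin(th2), 0.0])
    pos = np.array([s1, b1, b2, s2])
    cand = np.array([[1, 2]], dtype=np.int64)
    sugar_of = np.array([-1, 0, 3, -1], dtype=np.int64)
    code = np.array([-1, 0, 3, -1], dtype=np.int64)   # A pairs T
    two = lambda v: np.array([v, v])
    # phi0 = the dihedral of this planar cis geometry (0)
    args = (two(3.0), two(2.0), two(r0), two(th1), two(th2), two(0.0),
            two(gamma))
    F = np.zeros_like(pos)
    e_ref = K.basepair_ef(pos, cand, sugar_of, code, *args, 18.0,
                          box, False, F)
    assert e_ref == pytest.approx(-3.0, rel=1e-9)   # all modulators 1
    # rotate sugar 1 in-plane by 0.5 rad: dtheta1 = 0.5 >= 2*gamma
    pos2 = pos.copy()
    pos2[0] = b1 + 4.0 * np.array([np.cos(th1 + 0.5), np.sin(th1 + 0.5),
                                   0.0])
    F2 = np.zeros_like(pos)
    e_gated = K.basepair_ef(pos2, cand, sugar_of, code, *args, 18.0,
                            box, False, F2)
    assert e_gated == pytest.approx(0.0, abs=1e-12)
    assert np.abs(F2).max() == pytest.approx(0.0, abs=1e-12)


def test_non_wc_pair_contributes_nothing():
    from rescg import _kernels as K
    box = np.ones(3)
    pos = np.array([[0.0, 3, 0], [0, 0, 0], [5.6, 0, 0], [5.6, 3, 0]])
    cand = np.array([[1, 2]], dtype=np.int64)
    sugar_of = np.array([-1, 0, 3, -1], dtype=np.int64)
    code = np.array([-1, 0, 0, -1], dtype=np.int64)     # A against A
    one = np.array([1.0, 1.0])
    F = np.zeros_like(pos)
    e = K.basepair_ef(pos, cand, sugar_of, code, 3 * one, 2 * one,
                      5.6 * one, 2 * one, 2 * one, 0 * one, 0.3 * one,
                      18.0, box, False, F)
    assert e == 0.0


# ---------------------------------------------------------------------------
# model combination matrix
# ---------------------------------------------------------------------------

def test_ah_on_dna_rejected(duplex):
    top, _ = builder.generate_model_topology(duplex.cgmap, "3spn2c")
    top.particles.eps[:] = 0.2    # pretend AH parameters on DNA sites
    with pytest.raises(CombinationError):
        CGSystem(top)


def test_pwmcos_requires_protein_and_dna(dna_system):
    top, frame, _ = dna_system
    from rescg.topology import PWMcosSites
    top.pwmcos = PWMcosSites(*[np.zeros(1, dtype=np.int64)] * 5,
                             *[np.ones(1)] * 6)
    with pytest.raises(CombinationError):
        CGSystem(top)
    top.pwmcos = None


def test_ele_disabled_removes_term(dna_system):
    top, frame, _ = dna_system
    system = CGSystem(top, options={"ele": False})
    rep = system.energy_forces(frame)
    assert "ele" not in rep.terms
    rep_on = CGSystem(top).energy_forces(frame)
    assert "ele" in rep_on.terms
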