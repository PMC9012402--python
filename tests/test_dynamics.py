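"""Langevin velocity-Verlet integration: noise statistics, determinism,
energy conservation, the harmonic-oscillator period and equipartition."""

import math

import numpy as np
import pytest

from rescg import builder
from rescg.constants import ACCEL_CONV, KB
from rescg.dynamics import SimState, langevin_noise, run, step
from rescg.models import CGSystem
from rescg.neighbor import NeighborState
from rescg.topology import Bonds, CGTopology, Frame
from conftest import bare_particles


def free_particles(n=50, mass=110.0, seed=0):
    top = CGTopology(particles=bare_particles(
        n, chain=[f"C{i}" for i in range(n)], mass=mass))
    system = CGSystem(top)
    pos = np.random.default_rng(seed).random((n, 3)) * 100.0
    return system, Frame(pos)


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def test_noise_zero_without_friction():
    system, frame = free_particles(5)
    st = SimState.from_system(system, frame, friction=0.0, velocities=None)
    assert not langevin_noise(st).any()


def test_noise_variance_matches_closed_form():
    system, frame = free_particles(4, mass=120.0)
    st = SimState.from_system(system, frame, friction=1e-3, dt=10.0,
                              temperature=300.0, seed=3, velocities=None)
    draws = []
    for s in range(28000):       # ~1e6 component draws for one particle
        st.step = s
        draws.append(langevin_noise(st)[:3])
    draws = np.array(draws).ravel()
    m_int = 120.0 / ACCEL_CONV
    expected = 2 * 1e-3 * KB * 300.0 / (m_int * 10.0)
    assert len(draws) >= 1_000_000 * 0.25
    assert np.mean(draws) == pytest.approx(0.0, abs=5e-3 * math.sqrt(expected))
    assert np.var(draws) == pytest.approx(expected, rel=0.01)


def test_noise_stream_is_seed_deterministic():
    system, frame = free_particles(6)
    a = SimState.from_system(system, frame, friction=1e-3, seed=11,
                             velocities=None)
    b = SimState.from_system(system, frame, friction=1e-3, seed=11,
                             velocities=None)
    a.step = b.step = 42
    assert np.array_equal(langevin_noise(a), langevin_noise(b))
    b.seed = 12
    assert not np.array_equal(langevin_noise(a), langevin_noise(b))


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def test_zero_force_zero_velocity_is_static(three_bead_top):
    top, frame = three_bead_top
    # place exactly at the minimum: bond lengths 3.8, angle 1.9
    th = 1.9
    pos = np.array([[0.0, 0, 0], [3.8, 0, 0],
                    [3.8 - 3.8 * math.cos(th), 3.8 * math.sin(th), 0.0]])
    system = CGSystem(top)
    st = SimState.from_system(system, Frame(pos), friction=0.0,
                              velocities=None)
    nbs = NeighborState(system, 20)
    for _ in range(100):
        step(st, system, nbs)
    assert np.allclose(st.frame.positions, pos, atol=1e-10)


def test_harmonic_oscillator_period():
    top = CGTopology(particles=bare_particles(2, chain=["A", "A"],
                                              mass=100.0))
    top.particles.mass[0] = 1e12     # effectively fixed anchor
    top.bonds = Bonds(np.array([[0, 1]]), np.array([1]), np.array([3.8]),
                      np.array([100.0]), np.zeros(1))
    system = CGSystem(top)
    m_int = 100.0 / ACCEL_CONV
    period = 2 * math.pi / math.sqrt(2 * 100.0 / m_int)
    dt = period / 1000.0
    st = SimState.from_system(system, Frame(np.array([[0.0, 0, 0],
                                                      [3.9, 0, 0]])),
                              friction=0.0, dt=dt, velocities=None)
    nbs = NeighborState(system, 10 ** 9)
    crossings = []
    prev = st.frame.positions[1, 0] - 3.8
    for _ in range(2500):
        step(st, system, nbs)
        cur = st.frame.positions[1, 0] - 3.8
        if prev < 0 <= cur:
            crossings.append(st.frame.time - dt * cur / (cur - prev))
        prev = cur
    measured = (crossings[-1] - crossings[0]) / (len(crossings) - 1)
    assert measured == pytest.approx(period, rel=1e-3)


def test_nve_energy_conservation(three_bead_top):
    top, frame = three_bead_top
    system = CGSystem(top)
    st = SimState.from_system(system, frame, friction=0.0, dt=10.0,
                              velocities=None)
    nbs = NeighborState(system, 20)
    step(st, system, nbs)
    e0 = st.potential + st.kinetic_energy()
    drift = 0.0
    for _ in range(9999):
        step(st, system, nbs)
        drift = max(drift, abs(st.potential + st.kinetic_energy() - e0))
    assert drift / 3 < 1e-4        # kcal/mol per particle


def test_langevin_equipartition():
    system, frame = free_particles(50)
    st = SimState.from_system(system, frame, friction=1e-3, dt=10.0,
                              temperature=300.0, seed=7, velocities=None)
    nbs = NeighborState(system, 10 ** 9)
    kes = []
    for i in range(100_000):
        step(st, system, nbs)
        if i >= 2000:
            kes.append(st.kinetic_energy())
    target = 1.5 * 50 * KB * 300.0
    assert np.mean(kes) == pytest.approx(target, rel=0.03)


# ---------------------------------------------------------------------------
# run loop
# ---------------------------------------------------------------------------

def test_run_zero_steps_logs_initial_energy(tmp_path, three_bead_top):
    top, frame = three_bead_top
    system = CGSystem(top)
    st = SimState.from_system(system, frame, velocities=None)
    res = run(system, st, 0, traj_path=tmp_path / "z.dcd")
    assert res.frames_written == 0
    assert len(res.log) == 1
    assert "epot" in res.log[0]


def test_same_seed_runs_are_byte_identical(tmp_path):
    cg = builder.make_fixture("idp_chain", n=12, seed=1)
    top, frame = builder.generate_model_topology(cg, "hps")
    system = CGSystem(top)
    blobs = []
    for name in ("a.dcd", "b.dcd"):
        st = SimState.from_system(system, frame, friction=1e-3, seed=99)
        run(system, st, 500, traj_path=tmp_path / name, traj_stride=100,
            log_stride=0)
        blobs.append((tmp_path / name).read_bytes())
    assert blobs[0] == blobs[1]
    assert len(blobs[0]) > 0


def test_restart_continues_bit_identically():
    cg = builder.make_fixture("idp_chain", n=8, seed=2)
    top, frame = builder.generate_model_topology(cg, "hps")
    system = CGSystem(top)
    st = SimState.from_system(system, frame, friction=1e-3, seed=5)
    nbs = NeighborState(system, 20)
    for _ in range(100):
        step(st, system, nbs)
    blob = st.serialize(nbs)
    for _ in range(100):
        step(st, system, nbs)
    st2, nbs2 = SimState.restore(system, blob)
    for _ in range(100):
        step(st2, system, nbs2)
    assert np.array_equal(st.frame.positions, st2.frame.positions)


def test_nonfinite_positions_abort():
    system, frame = free_particles(3)
    st = SimState.from_system(system, frame, friction=0.0, velocities=None)
    st.frame.positions[0, 0] = np.nan
    # a bonded term would now produce NaN; free particles stay finite, so
    # attach a bond to force the evaluation through the energy path
    top = system.topology
    top.bonds = Bonds(np.array([[0, 1]]), np.array([1]), np.array([3.8]),
                      np.array([1.0]), np.zeros(1))
    system2 = CGSystem(top)
    st2 = SimState.from_system(system2, st.frame, friction=0.0,
                               velocities=None)
    nbs = NeighborState(system2, 20)
    with pytest.raises(FloatingPointError):
        step(st2, system2, nbs)
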