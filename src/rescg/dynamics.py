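"""Langevin dynamics with the velocity-Verlet integrator.

The equations of motion are integrated as

    v(t)      = v(t - dt) + dt * (F(t) + F(t - dt)) / (2 m)
    r(t + dt) = r(t) + dt * v(t) + dt^2 * F(t) / (2 m)

with the Langevin force

    F(t) = -grad V(r(t)) - m * gamma * v + m * xi(t)

where each component of the Gaussian noise xi satisfies
<xi^2> = 2 * gamma * kB * T / (m * dt).  The loop is the algebraically
equivalent half-kick / drift / half-kick form; the friction term uses the
half-step velocity.  With gamma = 0 and no noise the scheme reduces to
plain energy-conserving velocity Verlet.

Reproducibility: the noise stream is generated by a counter-based Philox
generator keyed by (seed, step), so trajectories are bit-identical for a
given seed regardless of how the work is scheduled, and a run can be
restarted mid-stream.

Masses are internally rescaled (``m_int = m / ACCEL_CONV``) so that
``F / m_int`` is in A/fs^2 and kinetic energies come out in kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .constants import ACCEL_CONV, KB, DEFAULT_DT, DEFAULT_FRICTION, \
    DEFAULT_NEIGHBOR_INTERVAL

_EMPTY = np.empty((0, 3))
from .neighbor import NeighborState
from .topology import Frame


def _noise_rng(seed: int, step: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=[seed, step]))


@dataclass
class SimState:
    """Mutable integrator state for one system."""
    frame: Frame
    masses_int: np.ndarray          # m / ACCEL_CONV
    temperature: float = 300.0
    friction: float = DEFAULT_FRICTION   # gamma, 1/fs
    dt: float = DEFAULT_DT               # fs
    seed: int = 0
    step: int = 0
    forces: np.ndarray | None = None     # potential gradient part, kcal/mol/A
    accel: np.ndarray | None = None      # full Langevin acceleration, A/fs^2
    potential: float = 0.0

    @classmethod
    def from_system(cls, system, frame: Frame, *, temperature=300.0,
                    friction=DEFAULT_FRICTION, dt=DEFAULT_DT, seed=0,
                    velocities="maxwell"):
        """Initialize from a topology-backed system.

        ``velocities`` may be an array, ``None`` (zeros), or ``"maxwell"``
        for a Maxwell-Boltzmann draw at ``temperature`` (seeded).
        """
        m_int = np.ascontiguousarray(
            system.topology.particles.mass / ACCEL_CONV)
        frame = Frame(frame.positions.copy(),
                      None if frame.velocities is None
                      else frame.velocities.copy(),
                      frame.box, frame.step, frame.time)
        if isinstance(velocities, str) and velocities == "maxwell":
            rng = _noise_rng(seed, -1 & 0x7FFFFFFF)
            sig = np.sqrt(KB * temperature / m_int)
            frame.velocities = rng.standard_normal(
                frame.positions.shape) * sig[:, None]
        elif velocities is None:
            frame.velocities = np.zeros_like(frame.positions)
        else:
            frame.velocities = np.ascontiguousarray(velocities, dtype=float)
        return cls(frame=frame, masses_int=m_int, temperature=temperature,
                   friction=friction, dt=dt, seed=seed)

    # -- thermodynamics ----------------------------------------------------
    def kinetic_energy(self) -> float:
        v = self.frame.velocities
        return float(0.5 * np.sum(self.masses_int[:, None] * v * v))

    def instantaneous_temperature(self) -> float:
        dof = 3 * len(self.masses_int)
        return 2.0 * self.kinetic_energy() / (dof * KB)

    # -- persistence -------------------------------------------------------
    def serialize(self, neighbor: "NeighborState | None" = None) -> dict:
        """Snapshot for bit-identical continuation.  Passing the run's
        :class:`NeighborState` includes the live pair lists, whose build
        phase and ordering otherwise perturb the floating-point summation
        order on restart."""
        blob = {"positions": self.frame.positions.copy(),
                "velocities": self.frame.velocities.copy(),
                "box": None if self.frame.box is None else self.frame.box.copy(),
                "step": self.step, "time": self.frame.time,
                "seed": self.seed, "dt": self.dt,
                "accel": None if self.accel is None else self.accel.copy(),
                "temperature": self.temperature, "friction": self.friction}
        if neighbor is not None and neighbor.lists is not None:
            L = neighbor.lists
            blob["neighbor"] = {
                "interval": neighbor.interval,
                "pairs": {k: v for k, v in L.pairs.items()},
                "params": {k: v for k, v in L.params.items()},
                "build_positions": L.build_positions.copy(),
                "age": L.steps_since_build}
        return blob

    @classmethod
    def restore(cls, system, blob: dict):
        """Rebuild (state, neighbor) from :meth:`serialize` output."""
        from .neighbor import NeighborLists
        st = cls.from_system(system, Frame(blob["positions"],
                                           blob["velocities"], blob["box"]),
                             temperature=blob["temperature"],
                             friction=blob["friction"], dt=blob["dt"],
                             seed=blob["seed"],
                             velocities=blob["velocities"])
        st.step = blob["step"]
        st.frame.time = blob["time"]
        if blob.get("accel") is not None:
            st.accel = blob["accel"].copy()
        nb_blob = blob.get("neighbor")
        neighbor = NeighborState(system,
                                 interval=(nb_blob or {}).get("interval", 20))
        if nb_blob is not None:
            neighbor.lists = NeighborLists(
                pairs=dict(nb_blob["pairs"]),
                build_positions=nb_blob["build_positions"].copy(),
                steps_since_build=nb_blob["age"],
                params=dict(nb_blob["params"]))
        return st, neighbor


def langevin_noise(state: SimState) -> np.ndarray:
    """Per-particle Gaussian noise xi(t) for the current step, A/fs^2.

    Component variance is 2*gamma*kB*T/(m_int*dt); independent across
    particles and steps; zero when gamma is zero.
    """
    if state.friction == 0.0:
        return np.zeros_like(state.frame.positions)
    rng = _noise_rng(state.seed, state.step)
    sig = np.sqrt(2.0 * state.friction * KB * state.temperature
                  / (state.masses_int * state.dt))
    return rng.standard_normal(state.frame.positions.shape) * sig[:, None]


def _assemble_accel(state: SimState, grad_forces: np.ndarray,
                    velocities: np.ndarray) -> np.ndarray:
    """Langevin acceleration: (F_pot - m*gamma*v + m*xi) / m."""
    a = grad_forces / state.masses_int[:, None]
    if state.friction != 0.0:
        a = a - state.friction * velocities + langevin_noise(state)
    return a


def _inv_m(state: SimState) -> np.ndarray:
    if not hasattr(state, "_inv_m_int"):
        state._inv_m_int = np.ascontiguousarray(1.0 / state.masses_int)
    return state._inv_m_int


def step(state: SimState, system, neighbor: NeighborState) -> SimState:
    """Advance one velocity-Verlet/Langevin step in place."""
    f = state.frame
    if state.accel is None:
        lists = neighbor.maybe_rebuild(f.positions, f.box)
        rep = system.energy_forces(f, lists=lists)
        state.forces = rep.forces
        state.potential = rep.total
        state.accel = _assemble_accel(state, rep.forces, f.velocities)
    dt = state.dt
    K.kick_drift(f.positions, f.velocities, state.accel, dt)
    state.step += 1
    f.step = state.step
    f.time += dt
    lists = neighbor.maybe_rebuild(f.positions, f.box)
    rep = system.energy_forces(f, lists=lists)
    if not np.isfinite(rep.total):
        raise FloatingPointError(
            f"non-finite energy/force at step {state.step} "
            f"(E = {rep.total})")
    state.forces = rep.forces
    state.potential = rep.total
    noise = langevin_noise(state) if state.friction != 0.0 else _EMPTY
    K.assemble_kick(f.velocities, state.accel, rep.forces, _inv_m(state),
                    state.friction, noise, dt)
    return state


@dataclass
class RunResult:
    state: SimState
    frames_written: int
    log: list = field(default_factory=list)


def run(system, state: SimState, nsteps: int, *,
        neighbor_interval: int = DEFAULT_NEIGHBOR_INTERVAL,
        traj_path=None, traj_stride: int = 1000,
        log_stride: int = 1000, log_stream=None,
        callback=None, callback_stride: int = 0) -> RunResult:
    """Run ``nsteps`` of Langevin dynamics.

    Writes DCD frames every ``traj_stride`` steps when ``traj_path`` is set,
    logs step/per-term energies/temperature every ``log_stride`` steps, and
    invokes ``callback(state)`` every ``callback_stride`` steps (a truthy
    return stops the run early).  With ``nsteps == 0`` the initial energy is
    still evaluated and logged.
    """
    from .io.dcd import DCDWriter

    neighbor = NeighborState(system, interval=neighbor_interval)
    result = RunResult(state=state, frames_written=0)

    def log_now():
        rep_terms = {"step": state.step, "epot": state.potential,
                     "temperature": state.instantaneous_temperature()}
        result.log.append(rep_terms)
        if log_stream is not None:
            log_stream.write(
                f"step {state.step:10d}  Epot {state.potential: .4f}  "
                f"T {rep_terms['temperature']:8.2f}\n")

    # initial evaluation (also primes state.accel)
    lists = neighbor.maybe_rebuild(state.frame.positions, state.frame.box)
    rep = system.energy_forces(state.frame, lists=lists)
    state.forces = rep.forces
    state.potential = rep.total
    state.accel = _assemble_accel(state, rep.forces, state.frame.velocities)
    log_now()

    writer = None
    try:
        if traj_path is not None:
            writer = DCDWriter(traj_path, system.n_particles)
        for _ in range(nsteps):
            step(state, system, neighbor)
            if writer is not None and state.step % traj_stride == 0:
                writer.write(state.frame)
                result.frames_written += 1
            if log_stride and state.step % log_stride == 0:
                log_now()
            if (callback is not None and callback_stride
                    and state.step % callback_stride == 0):
                if callback(state):
                    break
    finally:
        if writer is not None:
            writer.close()
    return result
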