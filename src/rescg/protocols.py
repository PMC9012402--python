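"""Higher-level simulation protocols built from the library pieces.

Currently: the slab condensation protocol for disordered-protein phase
separation -- build an HPS slab of IDP chains, relax it, run Langevin
dynamics and track the largest connected cluster of chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import builder, models
from .dynamics import SimState, step
from .neighbor import NeighborState
from .parameters import FUS_LC_SEQUENCE
from .topology import Frame

# Langevin friction for condensation runs, 1/fs (= 0.01/ps).  Low friction
# is the convention in slab simulations of IDP phase behavior: it
# accelerates chain diffusion without changing the equilibrium ensemble.
CONDENSATION_FRICTION = 1.0e-5


def build_idp_slab(n_chains: int = 20, box=(180.0, 180.0, 340.0),
                   sequence: str = FUS_LC_SEQUENCE, seed: int = 0,
                   min_dist: float = 6.0, collapse_steps: int = 30_000):
    """HPS system of ``n_chains`` IDP chains dispersed through a periodic
    slab box (A); returns (system, frame).

    Mirrors the usual slab preparation: a single chain is first simulated
    on its own (``collapse_steps`` of Langevin dynamics) and its final,
    compact conformation is replicated into the box at random positions
    and orientations without contacts closer than ``min_dist``.
    """
    box = np.asarray(box, dtype=float)
    n = len(sequence)
    template = builder.make_fixture("idp_chain", n=n, sequence=sequence,
                                    count=1, seed=seed)
    if collapse_steps:
        top1, frame1 = builder.generate_model_topology(template, "hps")
        builder.assign_charges(top1, "integer")
        sys1 = models.CGSystem(top1)
        st = SimState.from_system(sys1, frame1, temperature=300.0,
                                  friction=1e-3, dt=10.0, seed=seed + 500)
        nbs = NeighborState(sys1, 20)
        for _ in range(collapse_steps):
            step(st, sys1, nbs)
        template.positions = st.frame.positions.copy()
    placed, _ = builder.make_fixture(
        "multi_chain_slab", chain_positions=template.positions, box=box,
        n_chains=n_chains, seed=seed + 1, min_dist=min_dist)
    cg = builder.make_fixture("idp_chain", n=n, sequence=sequence,
                              count=n_chains, seed=seed)
    cg.positions = placed.reshape(-1, 3)
    top, _ = builder.generate_model_topology(cg, "hps")
    builder.assign_charges(top, "integer")
    system = models.CGSystem(top)
    return system, Frame(cg.positions.copy(), box=box)


def chain_cluster_fractions(positions, box, n_chains: int, chain_len: int,
                            contact_dist: float = 8.0) -> np.ndarray:
    """Connected chain clusters (two chains touch when any inter-chain bead
    pair is within ``contact_dist``); returns cluster sizes / n_chains,
    descending."""
    pts = np.mod(positions, box)
    tree = cKDTree(pts, boxsize=box)
    parent = list(range(n_chains))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in tree.query_pairs(contact_dist):
        ci, cj = i // chain_len, j // chain_len
        if ci != cj:
            ra, rb = find(ci), find(cj)
            if ra != rb:
                parent[ra] = rb
    sizes = np.bincount([find(c) for c in range(n_chains)],
                        minlength=n_chains)
    sizes = np.sort(sizes[sizes > 0])[::-1]
    return sizes / n_chains


@dataclass
class CondensationResult:
    seed: int
    steps_run: int
    largest_fraction: float
    history: list = field(default_factory=list)   # (step, fraction)


def run_condensation(system, frame, *, seed: int, n_chains: int,
                     chain_len: int, max_steps: int = 1_000_000,
                     check_every: int = 10_000, target: float = 0.95,
                     temperature: float = 300.0,
                     relax_steps: int = 2000) -> CondensationResult:
    """Langevin condensation run with early exit.

    A short small-step relaxation removes any residual close contacts from
    the initial packing, then the production run (dt = 10 fs, low friction)
    proceeds until the largest chain cluster reaches ``target`` of all
    chains or ``max_steps`` is exhausted.
    """
    if relax_steps:
        st = SimState.from_system(system, frame, temperature=temperature,
                                  friction=1e-3, dt=1.0, seed=seed + 1000)
        nbs = NeighborState(system, 20)
        for _ in range(relax_steps):
            step(st, system, nbs)
        frame = Frame(st.frame.positions.copy(), box=frame.box)
    st = SimState.from_system(system, frame, temperature=temperature,
                              friction=CONDENSATION_FRICTION, dt=10.0,
                              seed=seed)
    nbs = NeighborState(system, 20)
    res = CondensationResult(seed=seed, steps_run=0, largest_fraction=0.0)
    while st.step < max_steps:
        for _ in range(check_every):
            step(st, system, nbs)
        fr = chain_cluster_fractions(st.frame.positions, st.frame.box,
                                     n_chains, chain_len)
        res.history.append((st.step, float(fr[0])))
        res.largest_fraction = float(fr[0])
        res.steps_run = st.step
        if fr[0] >= target:
            break
    return res
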