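"""Shared fixtures: small deterministic systems built by the package's own
synthetic generators."""

import numpy as np
import pytest

from rescg import builder, models
from rescg.parameters import flexible_tables
from rescg.topology import (Angles, Bonds, CGTopology, Frame, Particles)


def bare_particles(n, mol_class="protein", residue="ALA", mass=100.0,
                   chain=None):
    return Particles(
        name=np.array(["CA"] * n, dtype=object),
        mol_class=np.array([mol_class] * n, dtype=object),
        residue=np.array([residue] * n, dtype=object),
        chain=np.array(chain if chain is not None else ["A"] * n,
                       dtype=object),
        resid=np.arange(1, n + 1, dtype=np.int64),
        mass=np.full(n, mass), charge=np.zeros(n), radius=np.zeros(n),
        lam=np.zeros(n), sigma=np.zeros(n), eps=np.zeros(n))


@pytest.fixture(scope="session")
def helix_model():
    return builder.make_fixture("helix_ca", n=20)


@pytest.fixture(scope="session")
def helix_cg(helix_model):
    return builder.map_protein(helix_model)


@pytest.fixture(scope="session")
def helix_system(helix_cg):
    top, frame = builder.generate_model_topology(helix_cg, "aicg2+")
    system = models.CGSystem(top, tables=flexible_tables())
    return top, frame, system


@pytest.fixture(scope="session")
def duplex():
    return builder.build_dsdna_from_sequence("CGCGATCGCG")


@pytest.fixture(scope="session")
def dna_system(duplex):
    top, frame = builder.generate_model_topology(duplex.cgmap, "3spn2c")
    builder.assign_charges(top, "integer")
    system = models.CGSystem(top)
    return top, frame, system


@pytest.fixture()
def three_bead_top():
    """Soft 3-bead bond/angle fixture near its energy minimum."""
    P = bare_particles(3)
    top = CGTopology(
        particles=P,
        bonds=Bonds(np.array([[0, 1], [1, 2]]), np.array([1, 1]),
                    np.array([3.8, 3.8]), np.array([1.0, 1.0]),
                    np.zeros(2)),
        angles=Angles(np.array([[0, 1, 2]]), np.array([1]),
                      np.array([1.9]), np.array([2.0]),
                      np.array([""], dtype=object)))
    th = 1.9
    p0 = np.zeros(3)
    p1 = np.array([3.8, 0.0, 0.0])
    p2 = p1 + 3.8 * np.array([-np.cos(th), np.sin(th), 0.0])
    pos = np.array([p0, p1, p2])
    pos[2, 2] += 0.05   # small perturbation to set the modes in motion
    return top, Frame(pos)


@pytest.fixture(scope="session")
def protein_dna_complex():
    """Helix placed against a short duplex, with PWMcos and HB sites
    detected from the native arrangement."""
    helix = builder.map_protein(builder.make_fixture("helix_ca", n=12))
    topp, fp = builder.generate_model_topology(helix, "aicg2+")
    build = builder.build_dsdna_from_sequence("CGCGTAAACG")
    topd, fd = builder.generate_model_topology(build.cgmap, "3spn2c")
    fp.positions += np.array([12.0, 0.0, 10.0])
    top, frame = builder.combine_topologies([topp, topd], [fp, fd])
    builder.assign_charges(top, "integer")
    top.pwmcos = builder.detect_pwmcos_sites(top, frame, pwm_length=10,
                                             cutoff=12.0)
    top.hbsites = builder.detect_hb_sites(top, frame, cutoff=12.0)
    return top, frame
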