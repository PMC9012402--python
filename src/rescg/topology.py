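"""Coarse-grained topology container and validation.

A :class:`CGTopology` holds everything the energy functions need besides the
coordinates: per-particle properties, bonded records, native contacts, DNA
base-interaction site lists, protein-DNA site records and the exclusion list.
Indices are 0-based and global across all molecule blocks; interaction records
store pairs with i < j.

Function-type integers (the closed reader/writer dialect):

================  ====  =============================
bonds             1     harmonic
                  21    quartic
angles            1     harmonic
                  21    tabulated (flexible/statistical)
dihedrals         1     periodic
                  21    Gaussian
                  22    tabulated
                  32    periodic, safe force evaluation
pairs             1     Go 12-10 native contact
                  2     12-6 Lennard-Jones
                  3     excluded volume r^-12
                  4     Gaussian
                  5     Morse
                  6     Ashbaugh-Hatch
================  ====  =============================
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np

BOND_FUNCS = {1: "harmonic", 21: "quartic"}
ANGLE_FUNCS = {1: "harmonic", 21: "tabulated"}
DIHEDRAL_FUNCS = {1: "periodic", 21: "gaussian", 22: "tabulated", 32: "periodic_safe"}
PAIR_FUNCS = {1: "go1210", 2: "lj126", 3: "exv12", 4: "gaussian",
              5: "morse", 6: "ashbaugh_hatch"}

PARTICLE_NAMES = ("CA", "DP", "DS", "DB", "RP", "RS", "RB", "NT")
MOL_CLASSES = ("protein", "dna", "rna")

BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
WC_PARTNER = {"A": "T", "T": "A", "C": "G", "G": "C", "U": "A"}


class TopologyError(ValueError):
    """Raised when a topology violates its invariants."""


def _arr(x, dtype):
    a = np.asarray(x, dtype=dtype)
    return a


@dataclass
class Particles:
    """Per-particle static properties (SoA layout)."""
    name: np.ndarray          # site tag, one of PARTICLE_NAMES
    mol_class: np.ndarray     # protein / dna / rna
    residue: np.ndarray       # residue or base identity (3/1-letter name)
    chain: np.ndarray         # chain id string
    resid: np.ndarray         # residue serial within chain (int)
    mass: np.ndarray          # amu
    charge: np.ndarray        # e
    radius: np.ndarray        # excluded-volume radius sigma_i ("varsigma"), A
    lam: np.ndarray           # hydropathy lambda (dimensionless)
    sigma: np.ndarray         # pair diameter for LJ/AH terms, A
    eps: np.ndarray           # pair well depth for LJ/AH terms, kcal/mol

    def __len__(self):
        return len(self.name)

    @classmethod
    def empty(cls):
        return cls(*[np.empty(0, dtype=object if i < 4 else float)
                     for i in range(11)])


@dataclass
class Bonds:
    idx: np.ndarray      # (n, 2) int
    func: np.ndarray     # (n,) int
    b0: np.ndarray       # A
    k1: np.ndarray       # harmonic k or quartic k2
    k2: np.ndarray       # quartic k4 (0 for harmonic)


@dataclass
class Angles:
    idx: np.ndarray      # (n, 3) int
    func: np.ndarray
    theta0: np.ndarray   # rad
    k: np.ndarray
    table: np.ndarray    # table id string ('' for harmonic)


@dataclass
class Dihedrals:
    idx: np.ndarray      # (n, 4) int
    func: np.ndarray
    phi0: np.ndarray     # rad
    mult: np.ndarray     # periodicity n (periodic kinds)
    k: np.ndarray        # k_phi or eps_phi
    sigma: np.ndarray    # Gaussian width, rad
    table: np.ndarray


@dataclass
class Contacts:
    """Go-type native contacts (pre-defined pairs, no cutoff)."""
    idx: np.ndarray      # (n, 2) int, i < j
    sigma: np.ndarray    # native distance, A
    eps: np.ndarray      # kcal/mol


@dataclass
class Gaussians13:
    """1-3 Gaussian local terms (AICG2+)."""
    idx: np.ndarray      # (n, 2) int
    r0: np.ndarray
    eps: np.ndarray
    w: np.ndarray


@dataclass
class StackSites:
    """Intra-strand base-stacking records: sugar, 5' base, 3' base."""
    idx: np.ndarray      # (n, 3) int: S_i, B_i, B_{i+1}
    eps: np.ndarray      # kcal/mol
    alpha: np.ndarray    # 1/A
    r0: np.ndarray       # A
    theta0: np.ndarray   # rad
    gamma: np.ndarray    # modulator half-width, rad


@dataclass
class BasePairSites:
    """Per-base data and per-WC-type parameters for base pairing/cross-stacking.

    ``base_idx`` lists every base particle eligible for pairing; ``sugar_idx``
    its sugar, ``base5/base3`` the sequence neighbors on the same strand (-1 at
    termini), ``code`` the base type (A=0,C=1,G=2,T=3).  ``pair_params`` has
    one row per WC combination key 'AT' and 'GC' with columns (eps, alpha, r0,
    theta1_0, theta2_0, phi0, gamma); ``cstk_params`` rows (eps, alpha, r0,
    theta3_0, thetaCS_0, gamma).
    """
    base_idx: np.ndarray
    sugar_idx: np.ndarray
    base5: np.ndarray
    base3: np.ndarray
    code: np.ndarray
    pair_params: dict
    cstk_params: dict


@dataclass
class PWMcosSites:
    """Sequence-specific protein-DNA recognition sites (one per native
    Calpha-base-pair contact and strand orientation)."""
    ca_idx: np.ndarray     # j
    ca_prev: np.ndarray    # j-1
    ca_next: np.ndarray    # j+1
    col: np.ndarray        # PWM column m
    strand: np.ndarray     # 0: column read directly, 1: complement row
    r0: np.ndarray
    theta1_0: np.ndarray
    theta2_0: np.ndarray
    theta3_0: np.ndarray
    w: np.ndarray          # Gaussian width, A
    gamma: np.ndarray      # modulator half-width, rad


@dataclass
class HBSites:
    """Sequence-nonspecific protein-DNA backbone hydrogen-bond sites."""
    p_idx: np.ndarray      # phosphate i
    s_idx: np.ndarray      # its sugar
    ca_idx: np.ndarray     # Calpha j
    ca_prev: np.ndarray
    ca_next: np.ndarray
    r0: np.ndarray
    theta1_0: np.ndarray
    theta2_0: np.ndarray
    eps: np.ndarray
    w: np.ndarray
    gamma: np.ndarray


@dataclass
class MoleculeBlock:
    name: str
    first: int            # first particle index (inclusive)
    last: int             # last particle index (exclusive)
    source: str = ""      # itp provenance


def _empty_int(shape):
    return np.empty(shape, dtype=np.int64)


def _empty_f(shape=0):
    return np.empty(shape, dtype=float)


@dataclass
class CGTopology:
    particles: Particles
    bonds: Bonds = field(default_factory=lambda: Bonds(
        _empty_int((0, 2)), _empty_int(0), _empty_f(), _empty_f(), _empty_f()))
    angles: Angles = field(default_factory=lambda: Angles(
        _empty_int((0, 3)), _empty_int(0), _empty_f(), _empty_f(),
        np.empty(0, dtype=object)))
    dihedrals: Dihedrals = field(default_factory=lambda: Dihedrals(
        _empty_int((0, 4)), _empty_int(0), _empty_f(), _empty_int(0),
        _empty_f(), _empty_f(), np.empty(0, dtype=object)))
    contacts: Contacts = field(default_factory=lambda: Contacts(
        _empty_int((0, 2)), _empty_f(), _empty_f()))
    gauss13: Gaussians13 = field(default_factory=lambda: Gaussians13(
        _empty_int((0, 2)), _empty_f(), _empty_f(), _empty_f()))
    stacks: StackSites | None = None
    basepairs: BasePairSites | None = None
    pwmcos: PWMcosSites | None = None
    hbsites: HBSites | None = None
    extra_exclusions: np.ndarray = field(
        default_factory=lambda: _empty_int((0, 2)))
    blocks: list = field(default_factory=list)

    # -- convenience -------------------------------------------------------
    @property
    def n_particles(self) -> int:
        return len(self.particles)

    def chain_of(self) -> np.ndarray:
        """Integer chain index per particle (chains in order of appearance)."""
        seen: dict = {}
        out = np.empty(self.n_particles, dtype=np.int64)
        for i, c in enumerate(self.particles.chain):
            out[i] = seen.setdefault(c, len(seen))
        return out

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        n = self.n_particles
        P = self.particles
        if n == 0:
            return
        for nm in P.name:
            if nm not in PARTICLE_NAMES:
                raise TopologyError(f"unknown particle name tag {nm!r}")
        for mc in P.mol_class:
            if mc not in MOL_CLASSES:
                raise TopologyError(f"unknown molecule class {mc!r}")
        if np.any(P.mass <= 0):
            raise TopologyError("particle masses must be positive")
        if np.any(P.radius < 0) or np.any(P.sigma < 0):
            raise TopologyError("radii must be non-negative")

        def check_idx(idx, what):
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise TopologyError(f"{what} index out of range")

        for rec, what in ((self.bonds.idx, "bond"), (self.angles.idx, "angle"),
                          (self.dihedrals.idx, "dihedral"),
                          (self.contacts.idx, "contact"),
                          (self.gauss13.idx, "1-3 gaussian")):
            check_idx(rec, what)
        for func in self.bonds.func:
            if func not in BOND_FUNCS:
                raise TopologyError(f"unknown bond function type {func}")
        for func in self.angles.func:
            if func not in ANGLE_FUNCS:
                raise TopologyError(f"unknown angle function type {func}")
        for func in self.dihedrals.func:
            if func not in DIHEDRAL_FUNCS:
                raise TopologyError(f"unknown dihedral function type {func}")
        if self.contacts.idx.size:
            if np.any(self.contacts.idx[:, 0] >= self.contacts.idx[:, 1]):
                raise TopologyError("contact pairs must be stored i < j")
            keys = self.contacts.idx[:, 0] * n + self.contacts.idx[:, 1]
            if len(np.unique(keys)) != len(keys):
                raise TopologyError("duplicate contact pairs")
            if np.any(self.contacts.sigma <= 0):
                raise TopologyError("contact sigma must be positive")
        if self.gauss13.idx.size and np.any(self.gauss13.w <= 0):
            raise TopologyError("1-3 gaussian width must be positive")
        if self.stacks is not None:
            check_idx(self.stacks.idx, "stack")
            if np.any(self.stacks.alpha <= 0):
                raise TopologyError("stack alpha must be positive")

    # -- exclusion bookkeeping --------------------------------------------
    def bonded_exclusions(self) -> set:
        """Pairs excluded from every generic nonbonded term: 1-2, 1-3 and
        dihedral 1-4 end pairs (plus the intermediate 1-2/1-3 pairs the
        records imply), as a set of (i, j) with i < j."""
        excl = set()
        for i, j in self.bonds.idx:
            excl.add((min(i, j), max(i, j)))
        for i, j, k in self.angles.idx:
            for a, b in ((i, j), (j, k), (i, k)):
                excl.add((min(a, b), max(a, b)))
        for i, j, k, l in self.dihedrals.idx:
            for a, b in ((i, j), (j, k), (k, l), (i, k), (j, l), (i, l)):
                excl.add((min(a, b), max(a, b)))
        for i, k in self.gauss13.idx:
            excl.add((min(i, k), max(i, k)))
        return excl

    def exv_exclusions(self) -> set:
        """Pairs additionally excluded from the excluded-volume term only:
        the bonded set plus native contacts, DNA stacking partners and the
        builder-declared extra pairs (native Watson-Crick partners)."""
        excl = self.bonded_exclusions()
        for i, j in self.contacts.idx:
            excl.add((min(i, j), max(i, j)))
        if self.stacks is not None:
            for s, b5, b3 in self.stacks.idx:
                excl.add((min(b5, b3), max(b5, b3)))
        for i, j in self.extra_exclusions:
            excl.add((min(i, j), max(i, j)))
        return excl

    def equal_to(self, other: "CGTopology", tol: float = 0.0) -> bool:
        """Field-for-field equality (used by the round-trip tests)."""
        if self.n_particles != other.n_particles:
            return False

        def eq(a, b):
            if isinstance(a, dict) or isinstance(b, dict):
                if not (isinstance(a, dict) and isinstance(b, dict)):
                    return False
                return set(a) == set(b) and all(eq(a[k], b[k]) for k in a)
            a, b = np.asarray(a), np.asarray(b)
            if a.shape != b.shape:
                return False
            if a.dtype.kind in "OU" or b.dtype.kind in "OU":
                return bool(np.all(a.astype(str) == b.astype(str)))
            if tol == 0.0:
                return bool(np.array_equal(a, b))
            return bool(np.allclose(a, b, atol=tol, rtol=0))

        for obj_a, obj_b in ((self.particles, other.particles),
                             (self.bonds, other.bonds),
                             (self.angles, other.angles),
                             (self.dihedrals, other.dihedrals),
                             (self.contacts, other.contacts),
                             (self.gauss13, other.gauss13)):
            for f in dc_fields(obj_a):
                if not eq(getattr(obj_a, f.name), getattr(obj_b, f.name)):
                    return False
        for a, b in ((self.stacks, other.stacks),
                     (self.pwmcos, other.pwmcos),
                     (self.hbsites, other.hbsites)):
            if (a is None) != (b is None):
                return False
            if a is not None:
                for f in dc_fields(a):
                    va, vb = getattr(a, f.name), getattr(b, f.name)
                    if isinstance(va, dict):
                        if set(va) != set(vb) or any(
                                not eq(va[k], vb[k]) for k in va):
                            return False
                    elif not eq(va, vb):
                        return False
        if (self.basepairs is None) != (other.basepairs is None):
            return False
        if self.basepairs is not None:
            a, b = self.basepairs, other.basepairs
            for f in dc_fields(a):
                va, vb = getattr(a, f.name), getattr(b, f.name)
                if isinstance(va, dict):
                    if set(va) != set(vb) or any(
                            not eq(va[k], vb[k]) for k in va):
                        return False
                elif not eq(va, vb):
                    return False
        return eq(np.sort(self.extra_exclusions, axis=0) if
                  self.extra_exclusions.size else self.extra_exclusions,
                  np.sort(other.extra_exclusions, axis=0) if
                  other.extra_exclusions.size else other.extra_exclusions)


@dataclass
class Frame:
    """One coordinate set: positions (A), optional velocities (A/fs),
    optional orthorhombic box lengths (A), step index and time (fs)."""
    positions: np.ndarray
    velocities: np.ndarray | None = None
    box: np.ndarray | None = None
    step: int = 0
    time: float = 0.0

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if self.velocities is not None:
            self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities must match positions shape")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be 3 strictly positive lengths")

    def check_against(self, top: CGTopology) -> None:
        if len(self.positions) != top.n_particles:
            raise ValueError(
                f"frame has {len(self.positions)} particles, topology "
                f"{top.n_particles}")
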