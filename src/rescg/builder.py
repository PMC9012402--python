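"""Build CG models from atomistic structures, sequences, or nothing at all.

This is the preparation stage of the framework: map atomistic structures to
one-bead-per-residue / three-beads-per-nucleotide CG particles, detect
native contacts, construct sequence-based dsDNA, attach model-specific
interaction records (AICG2+, HPS/KH, 3SPN.2C, structure-based RNA), assign
charges, and generate the deterministic synthetic fixtures used throughout
the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from . import parameters as par
from .dna_geometry import (COMPLEMENT, atoms_for, compose_frames,
                           site_position)
from .io.structure import AtomModel
from .topology import (BASE_CODES, BasePairSites, Bonds, Angles, CGTopology,
                       Contacts, Dihedrals, Frame, Gaussians13, HBSites,
                       MoleculeBlock, PWMcosSites, Particles, StackSites)

AA_SET = set(par.AA_THREE_TO_ONE)
NUC_SET = {"A", "C", "G", "T", "U"}


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------

@dataclass
class CGMap:
    """CG particles before model assignment: identity, mass, position and
    (when mapped from atoms) the heavy-atom group behind each bead."""
    name: np.ndarray
    mol_class: np.ndarray
    residue: np.ndarray
    chain: np.ndarray
    resid: np.ndarray
    mass: np.ndarray
    positions: np.ndarray
    groups: list | None = None
    source: AtomModel | None = None

    def __len__(self):
        return len(self.name)

    def chain_slices(self):
        """Yield (chain id, index array) in order of appearance."""
        if len(self) == 0:
            return
        start = 0
        for i in range(1, len(self) + 1):
            if i == len(self) or self.chain[i] != self.chain[start]:
                yield self.chain[start], np.arange(start, i)
                start = i


@dataclass
class MappingReport:
    """Audit of one atomistic-to-CG mapping."""
    per_chain: dict = field(default_factory=dict)   # chain -> {class: count}
    dropped: list = field(default_factory=list)     # (chain, resid, reason)

    @property
    def total(self) -> int:
        return sum(sum(d.values()) for d in self.per_chain.values())

    def add(self, chain, mol_class, count=1):
        self.per_chain.setdefault(chain, {}).setdefault(mol_class, 0)
        self.per_chain[chain][mol_class] += count


def _atom_masses(model: AtomModel, idx) -> float:
    return sum(par.ELEMENT_MASSES.get(str(model.element[i]).upper(), 12.011)
               for i in idx)


def _com(model: AtomModel, idx) -> np.ndarray:
    w = np.array([par.ELEMENT_MASSES.get(str(model.element[i]).upper(),
                                         12.011) for i in idx])
    return (model.positions[idx] * w[:, None]).sum(axis=0) / w.sum()


def map_protein(model: AtomModel, report: MappingReport | None = None
                ) -> CGMap:
    """One CG particle per amino-acid residue, centered on the Calpha atom."""
    report = report if report is not None else MappingReport()
    rows = []
    for chain, resid, resname, idx in model.residues():
        rn = par.canonical_residue(resname)
        if rn not in AA_SET:
            continue
        names = model.name[idx]
        ca = idx[names == "CA"]
        if len(ca) == 0:
            report.dropped.append((chain, resid, "no CA atom"))
            continue
        rows.append((chain, resid, rn, model.positions[ca[0]],
                     _atom_masses(model, idx), idx))
        report.add(chain, "protein")
    if not rows:
        raise ValueError("no mappable protein residues (zero CA atoms)")
    return CGMap(
        name=np.array(["CA"] * len(rows), dtype=object),
        mol_class=np.array(["protein"] * len(rows), dtype=object),
        residue=np.array([r[2] for r in rows], dtype=object),
        chain=np.array([r[0] for r in rows], dtype=object),
        resid=np.array([r[1] for r in rows], dtype=np.int64),
        mass=np.array([r[4] for r in rows]),
        positions=np.array([r[3] for r in rows]),
        groups=[r[5] for r in rows], source=model)


_P_ATOMS = {"P", "OP1", "OP2", "O1P", "O2P", "O5'"}
_S_ATOMS = {"C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O2'", "O3'"}


def map_nucleic(model: AtomModel, mol_class: str,
                report: MappingReport | None = None) -> CGMap:
    """Three CG particles (P, S, B) per nucleotide; the 5'-terminal
    nucleotide of each strand has no phosphate, so an n-nt strand maps to
    3n - 1 particles.  Beads sit at the center of mass of their group."""
    if mol_class not in ("dna", "rna"):
        raise ValueError("mol_class must be dna or rna")
    report = report if report is not None else MappingReport()
    tag = {"dna": ("DP", "DS", "DB"), "rna": ("RP", "RS", "RB")}[mol_class]
    rows = []
    prev_chain = None
    for chain, resid, resname, idx in model.residues():
        base = par.canonical_residue(resname)
        if base in AA_SET:
            continue
        if base not in NUC_SET:
            raise ValueError(
                f"unknown base identity {resname!r} in chain {chain}")
        names = model.name[idx]
        p_idx = idx[np.isin(names, list(_P_ATOMS))]
        s_idx = idx[np.isin(names, list(_S_ATOMS))]
        b_idx = idx[~np.isin(names, list(_P_ATOMS | _S_ATOMS))]
        first_of_chain = chain != prev_chain
        prev_chain = chain
        if len(s_idx) == 0 or len(b_idx) == 0:
            report.dropped.append((chain, resid, "incomplete nucleotide"))
            continue
        if len(p_idx) and not first_of_chain:
            rows.append((chain, resid, base, tag[0], _com(model, p_idx),
                         _atom_masses(model, p_idx), p_idx))
            report.add(chain, mol_class)
        rows.append((chain, resid, base, tag[1], _com(model, s_idx),
                     _atom_masses(model, s_idx), s_idx))
        rows.append((chain, resid, base, tag[2], _com(model, b_idx),
                     _atom_masses(model, b_idx), b_idx))
        report.add(chain, mol_class, 2)
    if not rows:
        raise ValueError("no mappable nucleotides")
    return CGMap(
        name=np.array([r[3] for r in rows], dtype=object),
        mol_class=np.array([mol_class] * len(rows), dtype=object),
        residue=np.array([r[2] for r in rows], dtype=object),
        chain=np.array([r[0] for r in rows], dtype=object),
        resid=np.array([r[1] for r in rows], dtype=np.int64),
        mass=np.array([r[5] for r in rows]),
        positions=np.array([r[4] for r in rows]),
        groups=[r[6] for r in rows], source=model)


def classify_chains(model: AtomModel) -> dict:
    """chain id -> 'protein' | 'dna' | 'rna' | 'other' by residue content."""
    out = {}
    for chain, residues in model.chains().items():
        kinds = set()
        has_o2p = False
        for rid, rn, idx in residues:
            cn = par.canonical_residue(rn)
            if cn in AA_SET:
                kinds.add("protein")
            elif cn in NUC_SET:
                kinds.add("nucleic")
                if cn == "U" or "O2'" in set(model.name[idx]):
                    has_o2p = True
        if kinds == {"protein"}:
            out[chain] = "protein"
        elif kinds == {"nucleic"}:
            out[chain] = "rna" if has_o2p else "dna"
        else:
            out[chain] = "other"
    return out


# ---------------------------------------------------------------------------
# native contacts
# ---------------------------------------------------------------------------

def detect_native_contacts(cgmap: CGMap, cutoff: float = 6.5,
                           min_seq_sep: int = 4, subset=None) -> Contacts:
    """Native contacts: CG pairs whose heavy-atom groups approach within
    ``cutoff`` in the reference structure.

    A pair qualifies if ANY heavy-atom pair distance is below the cutoff
    (counted once per CG pair); intra-chain pairs additionally need a
    residue separation of at least ``min_seq_sep``.  sigma is the native
    site-site distance; pairs are returned sorted with i < j.
    """
    if cgmap.groups is None or cgmap.source is None:
        raise ValueError("contact detection needs the atomistic source")
    sel = (np.arange(len(cgmap)) if subset is None
           else np.asarray(subset, dtype=np.int64))
    atom_xyz = []
    atom_owner = []
    for ci in sel:
        g = cgmap.groups[ci]
        atom_xyz.append(cgmap.source.positions[g])
        atom_owner.append(np.full(len(g), ci))
    atom_xyz = np.concatenate(atom_xyz)
    atom_owner = np.concatenate(atom_owner)
    tree = cKDTree(atom_xyz)
    pairs = set()
    for a, b in tree.query_pairs(cutoff):
        i, j = int(atom_owner[a]), int(atom_owner[b])
        if i == j:
            continue
        if i > j:
            i, j = j, i
        if (cgmap.chain[i] == cgmap.chain[j]
                and abs(int(cgmap.resid[i]) - int(cgmap.resid[j]))
                < min_seq_sep):
            continue
        pairs.add((i, j))
    idx = np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)
    sigma = (np.linalg.norm(cgmap.positions[idx[:, 0]]
                            - cgmap.positions[idx[:, 1]], axis=1)
             if len(idx) else np.empty(0))
    return Contacts(idx=idx, sigma=sigma, eps=np.full(len(idx), np.nan))


# ---------------------------------------------------------------------------
# sequence-to-structure dsDNA
# ---------------------------------------------------------------------------

@dataclass
class DuplexBuild:
    """Output of the sequence-to-structure builder."""
    atom_model: AtomModel
    cgmap: CGMap
    sequence: str
    frame_origins: np.ndarray
    frame_rotations: np.ndarray

    def base_cg_indices(self, strand: int) -> np.ndarray:
        """CG indices of base beads for one strand, 5'->3' order."""
        chain = "A" if strand == 0 else "B"
        mask = (self.cgmap.chain == chain) & (self.cgmap.name == "DB")
        return np.where(mask)[0]


def build_dsdna_from_sequence(seq: str, step_table=None) -> DuplexBuild:
    """Construct an idealized atomistic + CG dsDNA from a base sequence.

    Base-pair frames are composed from the sequence-dependent base-step
    parameter table (twist/tilt/roll/shift/slide/rise per dinucleotide);
    both strands are emitted with the complementary sequence, and the CG
    mapping is applied to the pseudo-atomistic model afterwards.
    """
    seq = seq.strip().upper()
    if len(seq) < 2:
        raise ValueError("sequence must have at least 2 bases")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"invalid DNA characters: {sorted(bad)}")
    table = step_table or par.base_step_table()
    steps = [table[seq[i:i + 2]] for i in range(len(seq) - 1)]
    origins, rots = compose_frames(steps)

    element, name, resname, chain, resid, pos = [], [], [], [], [], []

    def emit(strand, bp_index, base, serial):
        skip_p = ((strand == 0 and bp_index == 0)
                  or (strand == 1 and bp_index == len(seq) - 1))
        for aname, elem, local in atoms_for(base, strand):
            if skip_p and aname in _P_ATOMS:
                continue
            element.append(elem)
            name.append(aname)
            resname.append("D" + base)
            chain.append("A" if strand == 0 else "B")
            resid.append(serial)
            pos.append(origins[bp_index] + rots[bp_index] @ local)

    for i, b in enumerate(seq):               # strand I, 5'->3'
        emit(0, i, b, i + 1)
    for k in range(len(seq)):                 # strand II, its own 5'->3'
        i = len(seq) - 1 - k
        emit(1, i, COMPLEMENT[seq[i]], k + 1)

    model = AtomModel(element=np.array(element, dtype=object),
                      name=np.array(name, dtype=object),
                      resname=np.array(resname, dtype=object),
                      chain=np.array(chain, dtype=object),
                      resid=np.array(resid, dtype=np.int64),
                      positions=np.array(pos))
    cgmap = map_nucleic(model, "dna")
    return DuplexBuild(atom_model=model, cgmap=cgmap, sequence=seq,
                       frame_origins=origins, frame_rotations=rots)


# ---------------------------------------------------------------------------
# model topology generation
# ---------------------------------------------------------------------------

def _base_particles(topology: CGTopology) -> Particles:
    return topology.particles


def _particles_from_map(cgmap: CGMap) -> Particles:
    n = len(cgmap)
    return Particles(
        name=cgmap.name.copy(), mol_class=cgmap.mol_class.copy(),
        residue=cgmap.residue.copy(), chain=cgmap.chain.copy(),
        resid=cgmap.resid.copy(), mass=cgmap.mass.copy(),
        charge=np.zeros(n), radius=np.zeros(n), lam=np.zeros(n),
        sigma=np.zeros(n), eps=np.zeros(n))


def generate_model_topology(cgmap: CGMap, model: str, *,
                            flexible=None, contact_eps=None,
                            contact_cutoff=None, contacts=None,
                            intra_ele=False) -> tuple[CGTopology, Frame]:
    """Attach the interaction records one model's energy function requires.

    Parameters
    ----------
    cgmap : CGMap
        Mapped particles (single molecule class).
    model : {'aicg2+', 'hps', 'kh', '3spn2c', 'rna_struct'}
    flexible : optional dict chain -> set of resids
        AICG2+ flexible regions: these residues keep only local flexible
        terms (bond + tabulated angle/dihedral) -- no Gaussians, no
        contacts.
    contacts : optional precomputed Contacts (native-contact records).
    """
    classes = set(cgmap.mol_class)
    if model in ("aicg2+", "hps", "kh") and classes - {"protein", "rna"}:
        if model != "hps" or "dna" in classes:
            raise ValueError(f"model {model} cannot be applied to {classes}")
    if model == "3spn2c" and classes != {"dna"}:
        raise ValueError("3SPN.2C applies to DNA only")
    if model == "rna_struct" and classes != {"rna"}:
        raise ValueError("the structure-based RNA model applies to RNA only")
    if model == "aicg2+" and classes != {"protein"}:
        raise ValueError("AICG2+ applies to proteins only")

    builder = {"aicg2+": _build_aicg2p, "hps": _build_hps, "kh": _build_hps,
               "3spn2c": _build_3spn2c, "rna_struct": _build_rna}[model]
    top = builder(cgmap, model=model, flexible=flexible,
                  contact_eps=contact_eps, contact_cutoff=contact_cutoff,
                  contacts=contacts, intra_ele=intra_ele)
    top.validate()
    return top, Frame(cgmap.positions.copy())


def _geom(positions, idx):
    p = [positions[i] for i in idx]
    if len(idx) == 2:
        return float(np.linalg.norm(p[1] - p[0]))
    if len(idx) == 3:
        u, v = p[0] - p[1], p[2] - p[1]
        return float(np.arccos(np.clip(
            u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)))
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    m = np.cross(b1, b2)
    nv = np.cross(b2, b3)
    return float(np.arctan2(np.linalg.norm(b2) * (b1 @ nv), m @ nv))


def _empty_top(cgmap) -> CGTopology:
    return CGTopology(particles=_particles_from_map(cgmap))


def _build_aicg2p(cgmap, *, model, flexible, contact_eps, contact_cutoff,
                  contacts, **_):
    p = par.aicg2p_params()
    pos = cgmap.positions
    flexible = flexible or {}

    def is_flex(i):
        return int(cgmap.resid[i]) in flexible.get(cgmap.chain[i], ())

    top = _empty_top(cgmap)
    top.particles.radius[:] = p["exv_radius"]
    bonds, angles, dihedrals, gauss = [], [], [], []
    for chain, idx in cgmap.chain_slices():
        for a, b in zip(idx[:-1], idx[1:]):
            bonds.append((a, b, 1, _geom(pos, (a, b)), p["bond_k"], 0.0))
        for a, b, c in zip(idx[:-2], idx[1:-1], idx[2:]):
            angles.append((a, b, c, 21, 0.0, 0.0, "aicg_flex_angle"))
            if not (is_flex(a) or is_flex(b) or is_flex(c)):
                gauss.append((a, c, _geom(pos, (a, c)), p["gauss13_eps"],
                              p["gauss13_w"]))
        for quad in zip(idx[:-3], idx[1:-2], idx[2:-1], idx[3:]):
            a, b, c, d = quad
            dihedrals.append((a, b, c, d, 22, 0.0, 1, 0.0, 0.0,
                              "aicg_flex_dihedral"))
            if not any(is_flex(x) for x in quad):
                dihedrals.append((a, b, c, d, 21, _geom(pos, quad), 1,
                                  p["dihedral_gauss_eps"],
                                  p["dihedral_gauss_sigma"], ""))
    _fill_bonded(top, bonds, angles, dihedrals)
    if gauss:
        top.gauss13 = Gaussians13(
            idx=np.array([r[:2] for r in gauss], dtype=np.int64),
            r0=np.array([r[2] for r in gauss], dtype=float),
            eps=np.array([r[3] for r in gauss], dtype=float),
            w=np.array([r[4] for r in gauss], dtype=float))
    if contacts is None and cgmap.groups is not None:
        contacts = detect_native_contacts(
            cgmap, cutoff=contact_cutoff or p["contact_cutoff"])
    if contacts is not None and len(contacts.idx):
        keep = [n for n in range(len(contacts.idx))
                if not (is_flex(contacts.idx[n, 0])
                        or is_flex(contacts.idx[n, 1]))]
        eps = contacts.eps[keep]
        eps = np.where(np.isnan(eps), contact_eps or p["contact_eps"], eps)
        top.contacts = Contacts(idx=contacts.idx[keep],
                                sigma=contacts.sigma[keep], eps=eps)
    return top


def _build_hps(cgmap, *, model, **_):
    top = _empty_top(cgmap)
    P = top.particles
    prot = par.hps_table("kh" if model == "kh" else "hps")
    rna = par.hps_table("hps_rna")
    for i in range(len(cgmap)):
        if cgmap.mol_class[i] == "protein":
            row = prot.loc[str(cgmap.residue[i])]
        else:
            key = str(cgmap.residue[i])
            row = rna.loc["U" if key == "T" else key]
            P.name[i] = "NT"
        P.mass[i] = row["mass"]
        P.charge[i] = row["charge"]
        P.sigma[i] = row["sigma"]
        P.lam[i] = row["lambda"]
        P.eps[i] = row["eps"]
        P.radius[i] = row["sigma"] / 2.0   # cross-class exv combination
    bonds = []
    pos = cgmap.positions
    for chain, idx in cgmap.chain_slices():
        for a, b in zip(idx[:-1], idx[1:]):
            bonds.append((a, b, 1, 3.8 if cgmap.mol_class[a] == "protein"
                          else 5.0, 2.390, 0.0))
    _fill_bonded(top, bonds, [], [])
    return top


def _build_3spn2c(cgmap, *, model, contacts, **_):
    p = par.dna_params()
    pos = cgmap.positions
    top = _empty_top(cgmap)
    P = top.particles
    masses = p["site_masses"]
    for i in range(len(cgmap)):
        nm = cgmap.name[i]
        if nm == "DP":
            P.radius[i] = p["exv_radius"]["P"]
            if not cgmap.mass[i]:
                P.mass[i] = masses["P"]
        elif nm == "DS":
            P.radius[i] = p["exv_radius"]["S"]
            if not cgmap.mass[i]:
                P.mass[i] = masses["S"]
        else:
            P.radius[i] = p["exv_radius"]["B"]
            if not cgmap.mass[i]:
                P.mass[i] = masses[str(cgmap.residue[i])]

    bonds, angles, dihedrals, stacks = [], [], [], []
    base_rows = []
    bk = p["bond"]
    ak = p["angle"]["k"]
    dh = p["dihedral"]
    st = p["stack"]
    for chain, idx in cgmap.chain_slices():
        # regroup: file order is (P) S B per nucleotide
        nts = []
        cur = {}
        for i in idx:
            tagc = cgmap.name[i][1]   # P / S / B
            if tagc == "P":
                if cur:
                    nts.append(cur)
                cur = {"P": i}
            elif tagc == "S":
                if "S" in cur:
                    nts.append(cur)
                    cur = {}
                cur["S"] = i
            else:
                cur["B"] = i
        if cur:
            nts.append(cur)

        def bond(a, b):
            bonds.append((a, b, 21, _geom(pos, (a, b)), bk["k2"], bk["k4"]))

        def angle(a, b, c):
            angles.append((a, b, c, 1, _geom(pos, (a, b, c)), ak, ""))

        for k, nt in enumerate(nts):
            if "P" in nt:
                bond(nt["P"], nt["S"])
            bond(nt["S"], nt["B"])
            if k + 1 < len(nts):
                nxt = nts[k + 1]
                bond(nt["S"], nxt["P"])
                angle(nt["B"], nt["S"], nxt["P"])
                angle(nt["S"], nxt["P"], nxt["S"])
                if "P" in nt:
                    angle(nt["P"], nt["S"], nxt["P"])
                angle(nxt["P"], nxt["S"], nxt["B"])
                stacks.append((nt["S"], nt["B"], nxt["B"],
                               st["eps"], st["alpha"],
                               _geom(pos, (nt["B"], nxt["B"])),
                               _geom(pos, (nt["S"], nt["B"], nxt["B"])),
                               st["gamma"]))
            if k + 2 < len(nts):
                nxt, nxt2 = nts[k + 1], nts[k + 2]
                for quad in ((nt["S"], nxt["P"], nxt["S"], nxt2["P"]),):
                    phi = _geom(pos, quad)
                    dihedrals.append((*quad, 21, phi, 1, dh["gaussian_eps"],
                                      dh["gaussian_sigma"], ""))
                    dihedrals.append((*quad, 32, phi + math.pi, 1,
                                      dh["periodic_k"], 0.0, ""))
                if "P" in nt:
                    quad = (nt["P"], nt["S"], nxt["P"], nxt["S"])
                    phi = _geom(pos, quad)
                    dihedrals.append((*quad, 21, phi, 1, dh["gaussian_eps"],
                                      dh["gaussian_sigma"], ""))
                    dihedrals.append((*quad, 32, phi + math.pi, 1,
                                      dh["periodic_k"], 0.0, ""))
        for k, nt in enumerate(nts):
            base_rows.append((nt["B"], nt["S"],
                              nts[k - 1]["B"] if k > 0 else -1,
                              nts[k + 1]["B"] if k + 1 < len(nts) else -1,
                              BASE_CODES[str(cgmap.residue[nt["B"]])]))
    _fill_bonded(top, bonds, angles, dihedrals)
    top.stacks = StackSites(
        idx=np.array([r[:3] for r in stacks], dtype=np.int64).reshape(-1, 3),
        eps=np.array([r[3] for r in stacks]),
        alpha=np.array([r[4] for r in stacks]),
        r0=np.array([r[5] for r in stacks]),
        theta0=np.array([r[6] for r in stacks]),
        gamma=np.array([r[7] for r in stacks]))
    from .dna_geometry import (reference_cross_stack_geometry,
                               reference_pair_geometry)
    ref = reference_pair_geometry()
    cref = reference_cross_stack_geometry()
    pair_params = {}
    for key in ("AT", "GC"):
        bp = p["basepair"][key]
        pair_params[key] = {"eps": bp["eps"], "alpha": bp["alpha"],
                            "gamma": bp["gamma"], **ref}
    cs = p["cross_stack"]
    cstk_params = {key: {"eps": cs["eps"], "alpha": cs["alpha"],
                         "gamma": cs["gamma"], **cref} for key in ("AT", "GC")}
    top.basepairs = BasePairSites(
        base_idx=np.array([r[0] for r in base_rows], dtype=np.int64),
        sugar_idx=np.array([r[1] for r in base_rows], dtype=np.int64),
        base5=np.array([r[2] for r in base_rows], dtype=np.int64),
        base3=np.array([r[3] for r in base_rows], dtype=np.int64),
        code=np.array([r[4] for r in base_rows], dtype=np.int64),
        pair_params=pair_params, cstk_params=cstk_params)
    # native WC partners are excluded from exv: each base pairs with its
    # mutual nearest inter-strand neighbor (the native register)
    excl = []
    bidx = top.basepairs.base_idx
    if len(bidx) > 1:
        nearest = {}
        for a in range(len(bidx)):
            i = int(bidx[a])
            best = None
            for b in range(len(bidx)):
                j = int(bidx[b])
                if cgmap.chain[i] == cgmap.chain[j]:
                    continue
                d = float(np.linalg.norm(pos[i] - pos[j]))
                if d < 8.0 and (best is None or d < best[0]):
                    best = (d, j)
            if best is not None:
                nearest[i] = best[1]
        for i, j in nearest.items():
            if nearest.get(j) == i and i < j:
                excl.append((i, j))
    if excl:
        top.extra_exclusions = np.array(sorted(excl), dtype=np.int64)
    return top


def _build_rna(cgmap, *, model, contacts, contact_eps, contact_cutoff,
               intra_ele, **_):
    p = par.rna_params()
    pos = cgmap.positions
    top = _empty_top(cgmap)
    P = top.particles
    for i in range(len(cgmap)):
        site = cgmap.name[i][1]
        P.radius[i] = p["exv_radius"][site if site in "PS" else "B"]
        if not cgmap.mass[i]:
            key = site if site in "PS" else str(cgmap.residue[i])
            P.mass[i] = p["site_masses"][key]
    bonds, angles, dihedrals = [], [], []
    for chain, idx in cgmap.chain_slices():
        # connectivity from site pattern (P) S B | P S B ...
        sites = [(i, cgmap.name[i][1]) for i in idx]
        chain_bonds = []
        prev_s = None
        k = 0
        while k < len(sites):
            if sites[k][1] == "P":
                p_i = sites[k][0]
                s_i = sites[k + 1][0]
                b_i = sites[k + 2][0]
                chain_bonds += [(prev_s, p_i), (p_i, s_i), (s_i, b_i)]
                k += 3
            else:
                s_i = sites[k][0]
                b_i = sites[k + 1][0]
                chain_bonds += [(s_i, b_i)]
                k += 2
            prev_s = s_i
        for a, b in chain_bonds:
            if a is None:
                continue
            bonds.append((a, b, 1, _geom(pos, (a, b)), p["bond_k"], 0.0))
        # angles/dihedrals along the backbone path P-S-P-S...
        backbone = [i for i, t in sites if t in "PS"]
        for a, b, c in zip(backbone[:-2], backbone[1:-1], backbone[2:]):
            angles.append((a, b, c, 1, _geom(pos, (a, b, c)), p["angle_k"],
                           ""))
        for quad in zip(backbone[:-3], backbone[1:-2], backbone[2:-1],
                        backbone[3:]):
            phi = _geom(pos, quad)
            dihedrals.append((*quad, 32, phi + math.pi, 1, p["dihedral_k"],
                              0.0, ""))
    _fill_bonded(top, bonds, angles, dihedrals)
    if contacts is None and cgmap.groups is not None:
        contacts = detect_native_contacts(
            cgmap, cutoff=contact_cutoff or p["contact_cutoff"])
    if contacts is not None and len(contacts.idx):
        eps = np.where(np.isnan(contacts.eps),
                       contact_eps or p["contact_eps"], contacts.eps)
        top.contacts = Contacts(idx=contacts.idx, sigma=contacts.sigma,
                                eps=eps)
    return top


def _fill_bonded(top, bonds, angles, dihedrals):
    if bonds:
        top.bonds = Bonds(
            idx=np.array([r[:2] for r in bonds], dtype=np.int64),
            func=np.array([r[2] for r in bonds], dtype=np.int64),
            b0=np.array([r[3] for r in bonds], dtype=float),
            k1=np.array([r[4] for r in bonds], dtype=float),
            k2=np.array([r[5] for r in bonds], dtype=float))
    if angles:
        top.angles = Angles(
            idx=np.array([r[:3] for r in angles], dtype=np.int64),
            func=np.array([r[3] for r in angles], dtype=np.int64),
            theta0=np.array([r[4] for r in angles], dtype=float),
            k=np.array([r[5] for r in angles], dtype=float),
            table=np.array([r[6] for r in angles], dtype=object))
    if dihedrals:
        top.dihedrals = Dihedrals(
            idx=np.array([r[:4] for r in dihedrals], dtype=np.int64),
            func=np.array([r[4] for r in dihedrals], dtype=np.int64),
            phi0=np.array([_wrap(r[5]) for r in dihedrals], dtype=float),
            mult=np.array([r[6] for r in dihedrals], dtype=np.int64),
            k=np.array([r[7] for r in dihedrals], dtype=float),
            sigma=np.array([r[8] for r in dihedrals], dtype=float),
            table=np.array([r[9] for r in dihedrals], dtype=object))


def _wrap(x):
    y = math.fmod(x + math.pi, 2.0 * math.pi)
    if y <= 0.0:
        y += 2.0 * math.pi
    return y - math.pi


# ---------------------------------------------------------------------------
# charges
# ---------------------------------------------------------------------------

_POSITIVE = {"ARG", "LYS"}
_NEGATIVE = {"ASP", "GLU"}


def assign_charges(topology: CGTopology, scheme: str = "integer", *,
                   path=None, phosphate_scale: float = 1.0) -> CGTopology:
    """Set per-particle charges.

    ``scheme='integer'``: Arg/Lys +1 e, Asp/Glu -1 e, other residues 0;
    DNA/RNA phosphate beads (and one-bead nucleotides) -1 e times
    ``phosphate_scale``.

    ``scheme='file'``: two-column table (1-based particle index, charge);
    surface-charge output (e.g. RESPAC) is accepted as such a table.
    """
    P = topology.particles
    if scheme == "integer":
        for i in range(len(P)):
            res = str(P.residue[i])
            if P.mol_class[i] == "protein":
                P.charge[i] = (1.0 if res in _POSITIVE
                               else -1.0 if res in _NEGATIVE else 0.0)
            elif P.name[i] in ("DP", "RP", "NT"):
                P.charge[i] = -1.0 * phosphate_scale
            else:
                P.charge[i] = 0.0
    elif scheme == "file":
        if path is None:
            raise ValueError("file scheme needs a path")
        import pandas as pd
        df = pd.read_csv(path, comment="#",
                         names=["index", "charge"], header=None,
                         skipinitialspace=True)
        for _, row in df.iterrows():
            i = int(row["index"]) - 1
            if not 0 <= i < len(P):
                raise ValueError(
                    f"charge file references missing particle {i + 1}")
            P.charge[i] = float(row["charge"])
    else:
        raise ValueError(f"unknown charge scheme {scheme!r}")
    return topology


# ---------------------------------------------------------------------------
# protein-DNA site detection
# ---------------------------------------------------------------------------

def detect_pwmcos_sites(topology: CGTopology, frame: Frame, *,
                        pwm_length: int, bp_start_resid: int = 1,
                        cutoff: float = 8.0, w: float = 1.0,
                        gamma: float = 0.1745) -> PWMcosSites:
    """Native (Calpha, base) contacts -> PWMcos site records.

    Each contacting base within ``cutoff`` of a Calpha yields one site; the
    PWM column is the base-pair position (resid - ``bp_start_resid``);
    strand flag 1 marks the complementary strand (its columns read the
    complement row of the PWM).  Reference r0 and angles come from the
    native frame.
    """
    P = topology.particles
    pos = frame.positions
    bp = topology.basepairs
    if bp is None:
        raise ValueError("PWMcos site detection needs DNA base records")
    ca = np.where(P.name == "CA")[0]
    # interior Calphas only (need j-1, j+1 on the same chain)
    ca = np.array([j for j in ca
                   if j - 1 in ca and j + 1 in ca
                   and P.chain[j - 1] == P.chain[j] == P.chain[j + 1]],
                  dtype=np.int64)
    dna_chains = sorted({P.chain[i] for i in bp.base_idx})
    first_chain = dna_chains[0]
    rows = []
    tree = cKDTree(pos[ca]) if len(ca) else None
    for k, b in enumerate(bp.base_idx):
        col = int(P.resid[b]) - bp_start_resid
        if not 0 <= col < pwm_length:
            continue
        strand = 0 if P.chain[b] == first_chain else 1
        for jj in (tree.query_ball_point(pos[b], cutoff) if tree else ()):
            j = int(ca[jj])
            s = bp.sugar_idx[k]
            b5, b3 = bp.base5[k], bp.base3[k]
            if b5 < 0 or b3 < 0:
                continue
            r0 = float(np.linalg.norm(pos[j] - pos[b]))
            th1 = _geom(pos, (s, b, j))
            th2 = _vec_angle(pos[b3] - pos[b5], pos[j] - pos[b])
            th3 = _vec_angle(pos[j + 1] - pos[j - 1], pos[j] - pos[b])
            rows.append((j, j - 1, j + 1, col, strand, r0, th1, th2, th3))
    if not rows:
        raise ValueError("no protein-DNA base contacts found")
    rows.sort()
    return PWMcosSites(
        ca_idx=np.array([r[0] for r in rows], dtype=np.int64),
        ca_prev=np.array([r[1] for r in rows], dtype=np.int64),
        ca_next=np.array([r[2] for r in rows], dtype=np.int64),
        col=np.array([r[3] for r in rows], dtype=np.int64),
        strand=np.array([r[4] for r in rows], dtype=np.int64),
        r0=np.array([r[5] for r in rows]),
        theta1_0=np.array([r[6] for r in rows]),
        theta2_0=np.array([r[7] for r in rows]),
        theta3_0=np.array([r[8] for r in rows]),
        w=np.full(len(rows), w), gamma=np.full(len(rows), gamma))


def detect_hb_sites(topology: CGTopology, frame: Frame, *,
                    cutoff: float = 8.0, eps: float = 1.0, w: float = 1.0,
                    gamma: float = 0.1745) -> HBSites:
    """Native (phosphate, Calpha) contacts -> backbone HB site records."""
    P = topology.particles
    pos = frame.positions
    ca = np.where(P.name == "CA")[0]
    ca = np.array([j for j in ca
                   if j - 1 in ca and j + 1 in ca
                   and P.chain[j - 1] == P.chain[j] == P.chain[j + 1]],
                  dtype=np.int64)
    phos = np.where(np.isin(P.name, ["DP", "RP"]))[0]
    rows = []
    tree = cKDTree(pos[ca]) if len(ca) else None
    for p_i in phos:
        # sugar of the same nucleotide: next particle in the strand
        s_i = p_i + 1
        if s_i >= len(P) or P.name[s_i] not in ("DS", "RS"):
            continue
        for jj in (tree.query_ball_point(pos[p_i], cutoff) if tree else ()):
            j = int(ca[jj])
            r0 = float(np.linalg.norm(pos[j] - pos[p_i]))
            th1 = _geom(pos, (s_i, p_i, j))
            th2 = _vec_angle(pos[j + 1] - pos[j - 1], pos[j] - pos[p_i])
            rows.append((int(p_i), int(s_i), j, j - 1, j + 1, r0, th1, th2))
    if not rows:
        raise ValueError("no phosphate-Calpha contacts found")
    rows.sort()
    return HBSites(
        p_idx=np.array([r[0] for r in rows], dtype=np.int64),
        s_idx=np.array([r[1] for r in rows], dtype=np.int64),
        ca_idx=np.array([r[2] for r in rows], dtype=np.int64),
        ca_prev=np.array([r[3] for r in rows], dtype=np.int64),
        ca_next=np.array([r[4] for r in rows], dtype=np.int64),
        r0=np.array([r[5] for r in rows]),
        theta1_0=np.array([r[6] for r in rows]),
        theta2_0=np.array([r[7] for r in rows]),
        eps=np.full(len(rows), eps), w=np.full(len(rows), w),
        gamma=np.full(len(rows), gamma))


def _vec_angle(u, v) -> float:
    return float(np.arccos(np.clip(
        u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)))


# ---------------------------------------------------------------------------
# topology combination
# ---------------------------------------------------------------------------

def combine_topologies(tops: list[CGTopology],
                       frames: list[Frame]) -> tuple[CGTopology, Frame]:
    """Concatenate molecules into one system with global indices and one
    molecule block per input."""
    import dataclasses as dc

    def cat(vals, dtype=None):
        return np.concatenate([np.asarray(v) for v in vals])

    offs = np.cumsum([0] + [t.n_particles for t in tops])
    P = Particles(**{f.name: cat([getattr(t.particles, f.name)
                                  for t in tops])
                     for f in dc.fields(Particles)})
    # make chain ids unique across molecules
    chains = []
    for k, t in enumerate(tops):
        chains.extend(f"{c}:{k}" for c in t.particles.chain)
    P.chain = np.array(chains, dtype=object)
    out = CGTopology(particles=P)

    def shift(arrs, field_idx, off):
        a = getattr(arrs, field_idx).copy()
        a[a >= 0] += off
        return a

    for name, cls, idxfields in (
            ("bonds", Bonds, ("idx",)), ("angles", Angles, ("idx",)),
            ("dihedrals", Dihedrals, ("idx",)),
            ("contacts", Contacts, ("idx",)),
            ("gauss13", Gaussians13, ("idx",))):
        parts = {}
        for f in dc.fields(cls):
            vals = []
            for k, t in enumerate(tops):
                v = np.asarray(getattr(getattr(t, name), f.name))
                if f.name in idxfields:
                    v = v.copy()
                    v[v >= 0] += offs[k]
                vals.append(v)
            parts[f.name] = cat(vals)
        setattr(out, name, cls(**parts))
    stacks = [t.stacks for t in tops if t.stacks is not None]
    if stacks:
        out.stacks = StackSites(
            idx=np.concatenate([shift(t.stacks, "idx", offs[k])
                                for k, t in enumerate(tops)
                                if t.stacks is not None]),
            **{f: cat([getattr(t.stacks, f) for t in tops
                       if t.stacks is not None])
               for f in ("eps", "alpha", "r0", "theta0", "gamma")})
    bps = [(k, t.basepairs) for k, t in enumerate(tops)
           if t.basepairs is not None]
    if bps:
        out.basepairs = BasePairSites(
            base_idx=cat([shift(b, "base_idx", offs[k]) for k, b in bps]),
            sugar_idx=cat([shift(b, "sugar_idx", offs[k]) for k, b in bps]),
            base5=cat([shift(b, "base5", offs[k]) for k, b in bps]),
            base3=cat([shift(b, "base3", offs[k]) for k, b in bps]),
            code=cat([b.code for _, b in bps]),
            pair_params=bps[0][1].pair_params,
            cstk_params=bps[0][1].cstk_params)
    excl = []
    for k, t in enumerate(tops):
        if len(t.extra_exclusions):
            excl.append(t.extra_exclusions + offs[k])
    if excl:
        out.extra_exclusions = np.concatenate(excl)
    out.blocks = [MoleculeBlock(f"MOL{k + 1}", int(offs[k]),
                                int(offs[k + 1]))
                  for k in range(len(tops))]
    pos = np.concatenate([f.positions for f in frames])
    out.validate()
    return out, Frame(pos)


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str, **params):
    """Deterministic synthetic inputs for tests and examples.

    kinds: ``helix_ca`` (ideal alpha-helical pseudo-atomistic protein),
    ``idp_chain`` (self-avoiding-walk CG chains), ``toy_dsdna`` (sequence-
    built duplex), ``multi_chain_slab`` (replicated chains in a periodic
    box without close overlaps).
    """
    return {"helix_ca": _fixture_helix, "idp_chain": _fixture_idp,
            "toy_dsdna": _fixture_dsdna,
            "multi_chain_slab": _fixture_slab}[kind](**params)


def _fixture_helix(n=20, sequence=None) -> AtomModel:
    """Ideal alpha-helix with Calpha plus pseudo backbone/CB heavy atoms
    (radius 2.3 A, rise 1.5 A, 100 degrees per residue)."""
    omega = math.radians(100.0)
    rows = []
    seq = sequence or "A" * n
    if len(seq) != n:
        raise ValueError("sequence length mismatch")
    for i in range(n):
        a = i * omega
        u = np.array([math.cos(a), math.sin(a), 0.0])
        t = np.array([-math.sin(a), math.cos(a), 0.0])
        z = np.array([0.0, 0.0, 1.0])
        ca = 2.3 * u + 1.5 * i * z
        resname = par.AA_ONE_TO_THREE[seq[i]]
        atoms = [("N", "N", ca - 1.0 * t - 0.6 * z + 0.3 * u),
                 ("CA", "C", ca),
                 ("C", "C", ca + 1.0 * t + 0.4 * z + 0.3 * u),
                 ("O", "O", ca + 1.2 * t + 0.4 * z + 1.4 * u)]
        if resname != "GLY":
            atoms.append(("CB", "C", ca + 1.5 * u))
        for nm, el, p in atoms:
            rows.append((el, nm, resname, "A", i + 1, p))
    return AtomModel(
        element=np.array([r[0] for r in rows], dtype=object),
        name=np.array([r[1] for r in rows], dtype=object),
        resname=np.array([r[2] for r in rows], dtype=object),
        chain=np.array([r[3] for r in rows], dtype=object),
        resid=np.array([r[4] for r in rows], dtype=np.int64),
        positions=np.array([r[5] for r in rows]))


def _fixture_idp(n=100, sequence=None, count=1, seed=0, chain_prefix="I",
                 min_sep=4.2) -> CGMap:
    """Self-avoiding random-walk IDP chains at the CG level: bond 3.8 A and
    no non-bonded bead pair closer than ``min_sep`` anywhere along the
    chain.  Residues default to the FUS low-complexity sequence cycled to
    length n."""
    rng = np.random.default_rng(seed)
    if sequence is None:
        src = par.FUS_LC_SEQUENCE
        sequence = (src * (n // len(src) + 1))[:n]
    if len(sequence) != n:
        raise ValueError("sequence length mismatch")
    resnames = [par.AA_ONE_TO_THREE[c] for c in sequence]
    all_pos = []
    chains = []
    side = int(math.ceil(count ** (1 / 3)))
    spacing = 4.0 * math.sqrt(n) + 12.0  # ~ coil size, keeps chains apart

    def one_chain():
        # full self-avoidance; restart the walk on attrition
        for _restart in range(100):
            pos = np.zeros((n, 3))
            ok = True
            for i in range(1, n):
                for _try in range(200):
                    v = rng.standard_normal(3)
                    v *= 3.8 / np.linalg.norm(v)
                    cand = pos[i - 1] + v
                    prev = pos[:i - 1]
                    if (len(prev) == 0 or
                            np.min(np.einsum("ij,ij->i", prev - cand,
                                             prev - cand))
                            > min_sep * min_sep):
                        pos[i] = cand
                        break
                else:
                    ok = False
                    break
            if ok:
                return pos
        raise RuntimeError("self-avoiding walk failed")

    for c in range(count):
        offset = spacing * np.array([c % side, (c // side) % side,
                                     c // (side * side)], dtype=float)
        all_pos.append(one_chain() + offset)
        chains.extend([f"{chain_prefix}{c}"] * n)
    total = n * count
    return CGMap(
        name=np.array(["CA"] * total, dtype=object),
        mol_class=np.array(["protein"] * total, dtype=object),
        residue=np.array(resnames * count, dtype=object),
        chain=np.array(chains, dtype=object),
        resid=np.array(list(range(1, n + 1)) * count, dtype=np.int64),
        mass=np.array([par.hps_table().loc[r, "mass"]
                       for r in resnames] * count),
        positions=np.concatenate(all_pos))


def _fixture_dsdna(sequence=None, n_bp=None) -> DuplexBuild:
    if sequence is None:
        if n_bp is None:
            raise ValueError("give sequence or n_bp")
        sequence = ("CG" * n_bp)[:n_bp]
    return build_dsdna_from_sequence(sequence)


def _fixture_slab(chain_positions, box, n_chains, seed=0, min_dist=3.5,
                  max_tries=20000):
    """Replicate one chain into a periodic box with random placements and
    orientations, rejecting placements with inter-chain distances below
    ``min_dist``.  Returns (positions (n_chains, n, 3), box array)."""
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    template = np.asarray(chain_positions, dtype=float)
    template = template - template.mean(axis=0)
    placed = []
    tree = None
    pts = np.empty((0, 3))
    for c in range(n_chains):
        for attempt in range(max_tries):
            rot = Rotation.random(rng=rng).as_matrix()
            com = rng.random(3) * box
            cand = template @ rot.T + com
            wrapped = cand % box
            if tree is None:
                ok = True
            else:
                d, _ = tree.query(wrapped, k=1)
                ok = np.min(d) > min_dist
            if ok:
                placed.append(cand)
                pts = np.concatenate([pts, wrapped])
                tree = cKDTree(pts, boxsize=box)
                break
        else:
            raise RuntimeError(
                f"could not place chain {c} without overlaps "
                f"< {min_dist} A (impossible packing?)")
    return np.array(placed), box
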