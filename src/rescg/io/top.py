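"""GROMACS-dialect topology files (.top with #include'd .itp molecules).

One ``.itp`` per molecule block; cross-molecule records (inter-molecular Go
contacts, PWMcos/HB sites, extra exclusions) live in the ``.top`` after a
``[ intermolecular ]`` marker with global 1-based indices.  The dialect is
closed: every function type a writer can emit is accepted by the reader, and
unknown types or malformed records raise with file and line information.

Numbers are printed with repr-level precision so that
``read_topology(write_topology(T)) == T`` field for field.
"""

from __future__ import annotations

import os
from dataclasses import replace

import numpy as np

from ..topology import (ANGLE_FUNCS, BOND_FUNCS, DIHEDRAL_FUNCS, PAIR_FUNCS,
                        BasePairSites, Bonds, Angles, Dihedrals, CGTopology,
                        Contacts, Gaussians13, HBSites, MoleculeBlock,
                        PWMcosSites, Particles, StackSites, TopologyError)

_G = "%.17g"


class TopologyFileError(ValueError):
    def __init__(self, path, lineno, msg):
        super().__init__(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _fmt(*vals):
    out = []
    for v in vals:
        if isinstance(v, (int, np.integer)):
            out.append(str(int(v)))
        elif isinstance(v, str):
            out.append(v if v else "-")
        else:
            out.append(_G % float(v))
    return " ".join(out)


def _in_block(idx_row, first, last):
    return all(first <= i < last for i in idx_row)


def write_topology(topology: CGTopology, directory, prefix="system") -> str:
    """Write ``<prefix>.top`` plus one ``<prefix>_NN.itp`` per molecule
    block into ``directory``; returns the .top path."""
    topology.validate()
    os.makedirs(directory, exist_ok=True)
    blocks = topology.blocks or [MoleculeBlock("MOL1", 0,
                                               topology.n_particles)]
    itp_names = []
    for nb, blk in enumerate(blocks):
        name = f"{prefix}_{nb + 1:02d}.itp"
        _write_itp(topology, blk, os.path.join(directory, name))
        itp_names.append(name)
    top_path = os.path.join(directory, f"{prefix}.top")
    with open(top_path, "w") as fh:
        fh.write("; rescg topology\n")
        for name in itp_names:
            fh.write(f'#include "{name}"\n')
        fh.write("\n[ system ]\n")
        fh.write(f"{prefix}\n")
        fh.write("\n[ molecules ]\n")
        for blk in blocks:
            fh.write(f"{blk.name} 1\n")
        _write_intermolecular(topology, blocks, fh)
    return top_path


def _write_itp(top: CGTopology, blk: MoleculeBlock, path) -> None:
    P = top.particles
    f0, f1 = blk.first, blk.last
    with open(path, "w") as fh:
        fh.write("[ moleculetype ]\n")
        fh.write(f"{blk.name} 3\n")
        fh.write("\n[ atoms ]\n")
        fh.write("; nr class name resnr resname chain charge mass"
                 " radius lambda sigma eps\n")
        for i in range(f0, f1):
            fh.write(_fmt(i - f0 + 1, str(P.mol_class[i]), str(P.name[i]),
                          int(P.resid[i]), str(P.residue[i]),
                          str(P.chain[i]), P.charge[i], P.mass[i],
                          P.radius[i], P.lam[i], P.sigma[i], P.eps[i]) + "\n")

        def sec(title, idx, writer):
            rows = [n for n in range(len(idx))
                    if _in_block(idx[n], f0, f1)]
            fh.write(f"\n[ {title} ]\n")
            for n in rows:
                writer(n)

        b = top.bonds
        sec("bonds", b.idx, lambda n: fh.write(_fmt(
            b.idx[n, 0] - f0 + 1, b.idx[n, 1] - f0 + 1, int(b.func[n]),
            b.b0[n], b.k1[n], b.k2[n]) + "\n"))
        a = top.angles
        sec("angles", a.idx, lambda n: fh.write(_fmt(
            a.idx[n, 0] - f0 + 1, a.idx[n, 1] - f0 + 1, a.idx[n, 2] - f0 + 1,
            int(a.func[n]), a.theta0[n], a.k[n], str(a.table[n])) + "\n"))
        d = top.dihedrals
        sec("dihedrals", d.idx, lambda n: fh.write(_fmt(
            d.idx[n, 0] - f0 + 1, d.idx[n, 1] - f0 + 1, d.idx[n, 2] - f0 + 1,
            d.idx[n, 3] - f0 + 1, int(d.func[n]), d.phi0[n], int(d.mult[n]),
            d.k[n], d.sigma[n], str(d.table[n])) + "\n"))
        # pairs: func 1 = Go contact (sigma, eps); func 4 = 1-3 Gaussian
        fh.write("\n[ pairs ]\n")
        c = top.contacts
        for n in range(len(c.idx)):
            if _in_block(c.idx[n], f0, f1):
                fh.write(_fmt(c.idx[n, 0] - f0 + 1, c.idx[n, 1] - f0 + 1, 1,
                              c.sigma[n], c.eps[n]) + "\n")
        g = top.gauss13
        for n in range(len(g.idx)):
            if _in_block(g.idx[n], f0, f1):
                fh.write(_fmt(g.idx[n, 0] - f0 + 1, g.idx[n, 1] - f0 + 1, 4,
                              g.r0[n], g.eps[n], g.w[n]) + "\n")
        if top.stacks is not None:
            s = top.stacks
            fh.write("\n[ dna_stacks ]\n")
            for n in range(len(s.idx)):
                if _in_block(s.idx[n], f0, f1):
                    fh.write(_fmt(s.idx[n, 0] - f0 + 1, s.idx[n, 1] - f0 + 1,
                                  s.idx[n, 2] - f0 + 1, s.eps[n], s.alpha[n],
                                  s.r0[n], s.theta0[n], s.gamma[n]) + "\n")
        if top.basepairs is not None:
            bp = top.basepairs
            fh.write("\n[ dna_bases ]\n")
            for n in range(len(bp.base_idx)):
                if f0 <= bp.base_idx[n] < f1:
                    b5 = bp.base5[n]
                    b3 = bp.base3[n]
                    fh.write(_fmt(bp.base_idx[n] - f0 + 1,
                                  bp.sugar_idx[n] - f0 + 1,
                                  b5 - f0 + 1 if b5 >= 0 else 0,
                                  b3 - f0 + 1 if b3 >= 0 else 0,
                                  int(bp.code[n])) + "\n")


def _write_intermolecular(top: CGTopology, blocks, fh) -> None:
    ranges = [(b.first, b.last) for b in blocks]

    def cross(idx_row):
        return not any(all(f <= i < l for i in idx_row) for f, l in ranges)

    fh.write("\n[ intermolecular ]\n")
    c = top.contacts
    wrote = False
    rows = [n for n in range(len(c.idx)) if cross(c.idx[n])]
    if rows:
        fh.write("\n[ pairs ]\n")
        for n in rows:
            fh.write(_fmt(c.idx[n, 0] + 1, c.idx[n, 1] + 1, 1,
                          c.sigma[n], c.eps[n]) + "\n")
    if top.basepairs is not None:
        bp = top.basepairs
        fh.write("\n[ dna_bp_params ]\n")
        for key in ("AT", "GC"):
            p = bp.pair_params[key]
            fh.write(_fmt(key, p["eps"], p["alpha"], p["r0"], p["theta1_0"],
                          p["theta2_0"], p["phi0"], p["gamma"]) + "\n")
        fh.write("\n[ dna_cstk_params ]\n")
        for key in ("AT", "GC"):
            p = bp.cstk_params[key]
            fh.write(_fmt(key, p["eps"], p["alpha"], p["r0"], p["theta3_0"],
                          p["thetaCS_0"], p["gamma"]) + "\n")
    if top.pwmcos is not None:
        w = top.pwmcos
        fh.write("\n[ pwmcos ]\n")
        for n in range(len(w.ca_idx)):
            fh.write(_fmt(w.ca_idx[n] + 1, w.ca_prev[n] + 1,
                          w.ca_next[n] + 1, int(w.col[n]) + 1,
                          int(w.strand[n]), w.r0[n], w.theta1_0[n],
                          w.theta2_0[n], w.theta3_0[n], w.w[n],
                          w.gamma[n]) + "\n")
    if top.hbsites is not None:
        h = top.hbsites
        fh.write("\n[ hbsites ]\n")
        for n in range(len(h.p_idx)):
            fh.write(_fmt(h.p_idx[n] + 1, h.s_idx[n] + 1, h.ca_idx[n] + 1,
                          h.ca_prev[n] + 1, h.ca_next[n] + 1, h.r0[n],
                          h.theta1_0[n], h.theta2_0[n], h.eps[n], h.w[n],
                          h.gamma[n]) + "\n")
    if len(top.extra_exclusions):
        fh.write("\n[ exclusions ]\n")
        for i, j in top.extra_exclusions:
            fh.write(_fmt(i + 1, j + 1) + "\n")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _tokenize(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split(";")[0].strip()
            if line:
                yield lineno, line


def read_topology(top_path) -> CGTopology:
    """Parse a .top file and its #include'd .itp molecule files into one
    validated, globally 0-indexed :class:`CGTopology`."""
    directory = os.path.dirname(os.path.abspath(top_path))
    molecules = {}
    order = []
    inter_lines = []
    section = None
    intermolecular = False
    for lineno, line in _tokenize(top_path):
        if line.startswith("#include"):
            name = line.split(None, 1)[1].strip().strip('"')
            ipath = os.path.join(directory, name)
            if not os.path.exists(ipath):
                raise FileNotFoundError(
                    f"{top_path}:{lineno}: included file not found: {name}")
            mol = _read_itp(ipath)
            molecules[mol["name"]] = mol
            continue
        if line.startswith("["):
            section = line.strip("[] ").lower()
            if section == "intermolecular":
                intermolecular = True
            continue
        if intermolecular and section not in ("system", "molecules",
                                              "intermolecular"):
            inter_lines.append((section, lineno, line))
            continue
        if section == "molecules":
            parts = line.split()
            if len(parts) != 2:
                raise TopologyFileError(top_path, lineno,
                                        "expected: molname count")
            name, count = parts[0], int(parts[1])
            if name not in molecules:
                raise TopologyFileError(top_path, lineno,
                                        f"molecule {name!r} not #include'd")
            order.append((name, count))
        # [ system ] content ignored
    return _assemble(molecules, order, inter_lines, top_path)


_ITP_SECTIONS = ("moleculetype", "atoms", "bonds", "angles", "dihedrals",
                 "pairs", "dna_stacks", "dna_bases", "exclusions")


def _read_itp(path) -> dict:
    mol = {k: [] for k in _ITP_SECTIONS}
    mol["name"] = None
    section = None
    for lineno, line in _tokenize(path):
        if line.startswith("["):
            section = line.strip("[] ").lower()
            if section not in _ITP_SECTIONS:
                raise TopologyFileError(path, lineno,
                                        f"unknown section [ {section} ]")
            continue
        if section is None:
            raise TopologyFileError(path, lineno, "content before section")
        if section == "moleculetype":
            mol["name"] = line.split()[0]
            continue
        mol[section].append((lineno, line.split()))
    if mol["name"] is None:
        raise TopologyFileError(path, 0, "missing [ moleculetype ]")
    mol["path"] = path
    return mol


def _assemble(molecules, order, inter_lines, top_path) -> CGTopology:
    cols = {k: [] for k in ("name", "mol_class", "residue", "chain", "resid",
                            "mass", "charge", "radius", "lam", "sigma",
                            "eps")}
    bonds, angles, dihedrals, contacts, gauss = [], [], [], [], []
    stacks, dna_bases, excl = [], [], []
    blocks = []
    offset = 0
    chain_serial = 0
    for name, count in order:
        mol = molecules[name]
        path = mol["path"]
        natoms = len(mol["atoms"])
        for rep in range(count):
            chain_map = {}
            for lineno, t in mol["atoms"]:
                if len(t) != 12:
                    raise TopologyFileError(path, lineno,
                                            "atom record needs 12 fields")
                cols["mol_class"].append(t[1])
                cols["name"].append(t[2])
                cols["resid"].append(int(t[3]))
                cols["residue"].append(t[4])
                ch = t[5]
                if ch not in chain_map:
                    chain_map[ch] = f"{ch}@{chain_serial}" if count > 1 else ch
                cols["chain"].append(chain_map[ch] if count > 1 else ch)
                cols["charge"].append(float(t[6]))
                cols["mass"].append(float(t[7]))
                cols["radius"].append(float(t[8]))
                cols["lam"].append(float(t[9]))
                cols["sigma"].append(float(t[10]))
                cols["eps"].append(float(t[11]))
            chain_serial += 1

            def gi(tok, lineno):
                v = int(tok)
                if not 1 <= v <= natoms:
                    raise TopologyFileError(
                        path, lineno, f"index {v} out of molecule range")
                return v - 1 + offset

            for lineno, t in mol["bonds"]:
                func = int(t[2])
                if func not in BOND_FUNCS:
                    raise TopologyFileError(path, lineno,
                                            f"unknown bond function {func}")
                bonds.append((gi(t[0], lineno), gi(t[1], lineno), func,
                              float(t[3]), float(t[4]),
                              float(t[5]) if len(t) > 5 else 0.0))
            for lineno, t in mol["angles"]:
                func = int(t[3])
                if func not in ANGLE_FUNCS:
                    raise TopologyFileError(path, lineno,
                                            f"unknown angle function {func}")
                angles.append((gi(t[0], lineno), gi(t[1], lineno),
                               gi(t[2], lineno), func, float(t[4]),
                               float(t[5]), "" if t[6] == "-" else t[6]))
            for lineno, t in mol["dihedrals"]:
                func = int(t[4])
                if func not in DIHEDRAL_FUNCS:
                    raise TopologyFileError(
                        path, lineno, f"unknown dihedral function {func}")
                dihedrals.append((gi(t[0], lineno), gi(t[1], lineno),
                                  gi(t[2], lineno), gi(t[3], lineno), func,
                                  float(t[5]), int(t[6]), float(t[7]),
                                  float(t[8]), "" if t[9] == "-" else t[9]))
            for lineno, t in mol["pairs"]:
                func = int(t[2])
                if func == 1:
                    contacts.append((gi(t[0], lineno), gi(t[1], lineno),
                                     float(t[3]), float(t[4])))
                elif func == 4:
                    gauss.append((gi(t[0], lineno), gi(t[1], lineno),
                                  float(t[3]), float(t[4]), float(t[5])))
                elif func not in PAIR_FUNCS:
                    raise TopologyFileError(path, lineno,
                                            f"unknown pair function {func}")
                else:
                    raise TopologyFileError(
                        path, lineno,
                        f"pair function {func} not valid in [ pairs ]")
            for lineno, t in mol["dna_stacks"]:
                stacks.append((gi(t[0], lineno), gi(t[1], lineno),
                               gi(t[2], lineno), float(t[3]), float(t[4]),
                               float(t[5]), float(t[6]), float(t[7])))
            for lineno, t in mol["dna_bases"]:
                b5 = int(t[2])
                b3 = int(t[3])
                dna_bases.append((gi(t[0], lineno), gi(t[1], lineno),
                                  gi(str(b5), lineno) if b5 else -1,
                                  gi(str(b3), lineno) if b3 else -1,
                                  int(t[4])))
            for lineno, t in mol["exclusions"]:
                excl.append((gi(t[0], lineno), gi(t[1], lineno)))
            blocks.append(MoleculeBlock(name, offset, offset + natoms,
                                        source=path))
            offset += natoms

    n_total = offset
    bp_params = {}
    cstk_params = {}
    pwm_rows = []
    hb_rows = []
    for section, lineno, line in inter_lines:
        t = line.split()

        def gidx(tok):
            v = int(tok)
            if not 1 <= v <= n_total:
                raise TopologyFileError(top_path, lineno,
                                        f"global index {v} out of range")
            return v - 1

        if section == "pairs":
            if int(t[2]) != 1:
                raise TopologyFileError(top_path, lineno,
                                        "intermolecular pairs must be Go")
            contacts.append((gidx(t[0]), gidx(t[1]), float(t[3]),
                             float(t[4])))
        elif section == "dna_bp_params":
            bp_params[t[0]] = dict(zip(
                ("eps", "alpha", "r0", "theta1_0", "theta2_0", "phi0",
                 "gamma"), map(float, t[1:8])))
        elif section == "dna_cstk_params":
            cstk_params[t[0]] = dict(zip(
                ("eps", "alpha", "r0", "theta3_0", "thetaCS_0", "gamma"),
                map(float, t[1:7])))
        elif section == "pwmcos":
            pwm_rows.append((gidx(t[0]), gidx(t[1]), gidx(t[2]),
                             int(t[3]) - 1, int(t[4]), *map(float, t[5:11])))
        elif section == "hbsites":
            hb_rows.append((gidx(t[0]), gidx(t[1]), gidx(t[2]), gidx(t[3]),
                            gidx(t[4]), *map(float, t[5:11])))
        elif section == "exclusions":
            excl.append((gidx(t[0]), gidx(t[1])))
        else:
            raise TopologyFileError(top_path, lineno,
                                    f"unknown intermolecular section "
                                    f"[ {section} ]")

    # canonical contact order (i, j); keeps round-trips stable when contacts
    # are split between molecule files and the intermolecular section
    contacts.sort(key=lambda r: (r[0], r[1]))

    def arr(rows, i, dtype=float):
        return np.array([r[i] for r in rows], dtype=dtype)

    def idx2(rows, k):
        return (np.array([r[:k] for r in rows], dtype=np.int64)
                if rows else np.empty((0, k), dtype=np.int64))

    particles = Particles(
        name=np.array(cols["name"], dtype=object),
        mol_class=np.array(cols["mol_class"], dtype=object),
        residue=np.array(cols["residue"], dtype=object),
        chain=np.array(cols["chain"], dtype=object),
        resid=np.array(cols["resid"], dtype=np.int64),
        mass=np.array(cols["mass"]), charge=np.array(cols["charge"]),
        radius=np.array(cols["radius"]), lam=np.array(cols["lam"]),
        sigma=np.array(cols["sigma"]), eps=np.array(cols["eps"]))
    top = CGTopology(
        particles=particles,
        bonds=Bonds(idx2(bonds, 2), arr(bonds, 2, np.int64) if bonds
                    else np.empty(0, np.int64),
                    arr(bonds, 3) if bonds else np.empty(0),
                    arr(bonds, 4) if bonds else np.empty(0),
                    arr(bonds, 5) if bonds else np.empty(0)),
        angles=Angles(idx2(angles, 3),
                      arr(angles, 3, np.int64) if angles
                      else np.empty(0, np.int64),
                      arr(angles, 4) if angles else np.empty(0),
                      arr(angles, 5) if angles else np.empty(0),
                      np.array([r[6] for r in angles], dtype=object)
                      if angles else np.empty(0, dtype=object)),
        dihedrals=Dihedrals(idx2(dihedrals, 4),
                            arr(dihedrals, 4, np.int64) if dihedrals
                            else np.empty(0, np.int64),
                            arr(dihedrals, 5) if dihedrals else np.empty(0),
                            arr(dihedrals, 6, np.int64) if dihedrals
                            else np.empty(0, np.int64),
                            arr(dihedrals, 7) if dihedrals else np.empty(0),
                            arr(dihedrals, 8) if dihedrals else np.empty(0),
                            np.array([r[9] for r in dihedrals], dtype=object)
                            if dihedrals else np.empty(0, dtype=object)),
        contacts=Contacts(idx2(contacts, 2),
                          arr(contacts, 2) if contacts else np.empty(0),
                          arr(contacts, 3) if contacts else np.empty(0)),
        gauss13=Gaussians13(idx2(gauss, 2),
                            arr(gauss, 2) if gauss else np.empty(0),
                            arr(gauss, 3) if gauss else np.empty(0),
                            arr(gauss, 4) if gauss else np.empty(0)),
        extra_exclusions=idx2(excl, 2),
        blocks=blocks)
    if stacks:
        top.stacks = StackSites(idx2(stacks, 3), arr(stacks, 3),
                                arr(stacks, 4), arr(stacks, 5),
                                arr(stacks, 6), arr(stacks, 7))
    if dna_bases:
        top.basepairs = BasePairSites(
            base_idx=arr(dna_bases, 0, np.int64),
            sugar_idx=arr(dna_bases, 1, np.int64),
            base5=arr(dna_bases, 2, np.int64),
            base3=arr(dna_bases, 3, np.int64),
            code=arr(dna_bases, 4, np.int64),
            pair_params=bp_params, cstk_params=cstk_params)
    if pwm_rows:
        top.pwmcos = PWMcosSites(
            ca_idx=arr(pwm_rows, 0, np.int64),
            ca_prev=arr(pwm_rows, 1, np.int64),
            ca_next=arr(pwm_rows, 2, np.int64),
            col=arr(pwm_rows, 3, np.int64),
            strand=arr(pwm_rows, 4, np.int64),
            r0=arr(pwm_rows, 5), theta1_0=arr(pwm_rows, 6),
            theta2_0=arr(pwm_rows, 7), theta3_0=arr(pwm_rows, 8),
            w=arr(pwm_rows, 9), gamma=arr(pwm_rows, 10))
    if hb_rows:
        top.hbsites = HBSites(
            p_idx=arr(hb_rows, 0, np.int64), s_idx=arr(hb_rows, 1, np.int64),
            ca_idx=arr(hb_rows, 2, np.int64),
            ca_prev=arr(hb_rows, 3, np.int64),
            ca_next=arr(hb_rows, 4, np.int64),
            r0=arr(hb_rows, 5), theta1_0=arr(hb_rows, 6),
            theta2_0=arr(hb_rows, 7), eps=arr(hb_rows, 8),
            w=arr(hb_rows, 9), gamma=arr(hb_rows, 10))
    top.validate()
    return top
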