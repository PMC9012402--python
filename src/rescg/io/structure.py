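"""Atomistic structure input (PDB / PDBx-mmCIF via gemmi) and PDB output.

Heavy atoms are kept with their chain/residue hierarchy; hydrogens and
waters are dropped before mapping; alternate locations resolve to the
highest-occupancy conformer.  Both dialects of the same structure produce
identical :class:`AtomModel` contents.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np

_WATER = {"HOH", "WAT", "H2O", "DOD"}


@dataclass
class AtomModel:
    """Flat heavy-atom table: element symbol, atom name, residue name,
    chain id, residue sequence id, position (A)."""
    element: np.ndarray
    name: np.ndarray
    resname: np.ndarray
    chain: np.ndarray
    resid: np.ndarray
    positions: np.ndarray

    def __len__(self):
        return len(self.name)

    def residues(self):
        """Iterate (chain, resid, resname, atom-index array) in file order."""
        if len(self) == 0:
            return
        keys = list(zip(self.chain, self.resid))
        start = 0
        for i in range(1, len(self) + 1):
            if i == len(self) or keys[i] != keys[start]:
                yield (self.chain[start], int(self.resid[start]),
                       self.resname[start], np.arange(start, i))
                start = i

    def chains(self):
        out = {}
        for c, rid, rn, idx in self.residues():
            out.setdefault(c, []).append((rid, rn, idx))
        return out


def read_structure(path) -> AtomModel:
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: empty structure")
    st.setup_entities()
    model = st[0]
    element, name, resname, chain, resid, pos = [], [], [], [], [], []
    n_heavy = 0
    for ch in model:
        for res in ch:
            if res.name in _WATER:
                continue
            # resolve altlocs to the highest-occupancy conformer per atom name
            best: dict = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            if not best:
                continue
            for atom in best.values():
                element.append(atom.element.name)
                name.append(atom.name)
                resname.append(res.name)
                chain.append(ch.name)
                resid.append(res.seqid.num)
                pos.append([atom.pos.x, atom.pos.y, atom.pos.z])
                n_heavy += 1
    if n_heavy == 0:
        raise ValueError(f"{path}: no heavy atoms found")
    return AtomModel(element=np.array(element, dtype=object),
                     name=np.array(name, dtype=object),
                     resname=np.array(resname, dtype=object),
                     chain=np.array(chain, dtype=object),
                     resid=np.array(resid, dtype=np.int64),
                     positions=np.array(pos, dtype=float))


def write_pdb(model: AtomModel, path) -> None:
    st = gemmi.Structure()
    st.name = "rescg"
    md = gemmi.Model("1")
    chains: dict = {}
    for i in range(len(model)):
        cname = str(model.chain[i])
        if cname not in chains:
            chains[cname] = gemmi.Chain(cname)
        ch = chains[cname]
        rid = int(model.resid[i])
        if len(ch) == 0 or ch[-1].seqid.num != rid:
            res = gemmi.Residue()
            res.name = str(model.resname[i])
            res.seqid = gemmi.SeqId(rid, " ")
            ch.add_residue(res)
        atom = gemmi.Atom()
        atom.name = str(model.name[i])
        atom.element = gemmi.Element(str(model.element[i]))
        atom.pos = gemmi.Position(*model.positions[i])
        ch[-1].add_atom(atom)
    for ch in chains.values():
        md.add_chain(ch)
    st.add_model(md)
    st.write_pdb(str(path))
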