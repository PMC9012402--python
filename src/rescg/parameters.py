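"""Packaged parameter data: loading and caching.

All numeric model parameters ship as plain-text files under
``rescg/data/`` with documented schemas so users can substitute their own
(e.g. statistical flexible-term tables, sequence-dependent contact
energies, alternative hydropathy scales).  This module is the only place
that touches those files.
"""

from __future__ import annotations

import functools
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .dna_geometry import COMPLEMENT
from .potentials import SplineTable

AA_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_ONE_TO_THREE = {v: k for k, v in AA_THREE_TO_ONE.items()}

# common PDB residue-name aliases
RESIDUE_ALIASES = {"HSD": "HIS", "HSE": "HIS", "HSP": "HIS", "HID": "HIS",
                   "HIE": "HIS", "CYX": "CYS", "MSE": "MET",
                   "DA": "A", "DT": "T", "DG": "G", "DC": "C",
                   "RA": "A", "RU": "U", "RG": "G", "RC": "C"}

ELEMENT_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                  "P": 30.974, "S": 32.06, "SE": 78.971}


def canonical_residue(name: str) -> str:
    name = name.strip().upper()
    return RESIDUE_ALIASES.get(name, name)


def _path(name):
    return resources.files("rescg.data").joinpath(name)


@functools.lru_cache
def hps_table(kind: str = "hps") -> pd.DataFrame:
    fname = {"hps": "hps_protein.csv",
             "kh": "kh_pair_table_synthetic.csv",
             "hps_rna": "hps_rna.csv"}[kind]
    with resources.as_file(_path(fname)) as p:
        return pd.read_csv(p, comment="#").set_index("residue")


@functools.lru_cache
def aicg2p_params() -> dict:
    return yaml.safe_load(_path("aicg2p.yaml").read_text())


@functools.lru_cache
def dna_params() -> dict:
    return yaml.safe_load(_path("dna_3spn2c.yaml").read_text())


@functools.lru_cache
def rna_params() -> dict:
    return yaml.safe_load(_path("rna_struct.yaml").read_text())


@functools.lru_cache
def base_step_table() -> dict:
    """Step parameters for all 16 dinucleotides (complement-completed)."""
    with resources.as_file(_path("base_step.csv")) as p:
        df = pd.read_csv(p, comment="#")
    table = {}
    for _, row in df.iterrows():
        key = row["step"]
        vals = (row["twist"], row["tilt"], row["roll"],
                row["shift"], row["slide"], row["rise"])
        table[key] = vals
        # complementary step read on the other strand: reverse-complement
        # key; twist/roll/rise invariant, tilt/shift change sign
        rc = COMPLEMENT[key[1]] + COMPLEMENT[key[0]]
        if rc not in table:
            table[rc] = (vals[0], -vals[1], vals[2],
                         -vals[3], vals[4], vals[5])
    assert len(table) == 16
    return table


@functools.lru_cache
def flexible_tables() -> dict[str, SplineTable]:
    """Generic flexible-angle/dihedral spline tables (replaceable data)."""
    out = {}
    with resources.as_file(_path("aicg_flex_angle.csv")) as p:
        df = pd.read_csv(p, comment="#")
    out["aicg_flex_angle"] = SplineTable(df["theta"].to_numpy(),
                                         df["energy"].to_numpy())
    with resources.as_file(_path("aicg_flex_dihedral.csv")) as p:
        df = pd.read_csv(p, comment="#")
    out["aicg_flex_dihedral"] = SplineTable(df["phi"].to_numpy(),
                                            df["energy"].to_numpy(),
                                            periodic=True)
    return out


def load_spline_table(path, periodic=False) -> SplineTable:
    """User-supplied two-column table -> spline (same schema as packaged)."""
    df = pd.read_csv(path, comment="#")
    cols = df.columns
    return SplineTable(df[cols[0]].to_numpy(), df[cols[1]].to_numpy(),
                      periodic=periodic)


# FUS low-complexity domain (residues 1-163), the standard IDR condensation
# test sequence used by the synthetic slab generator
FUS_LC_SEQUENCE = (
    "MASNDYTQQATQSYGAYPTQPGQGYSQQSSQPYGQQSYSGYSQSTDTSGYGQSSYSSYGQ"
    "SQNTGYGTQSTPQGYGSTGGYGSSQSSQSSYGQQSSYPGYGQQPAPSSTSGSYGSSSQSS"
    "SYGQPQSGSYSQQPSYGGQQQSYGQQQSYNPPQGYGQQNQYNS")
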