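"""INI-style MD control files.

Sections: [input], [output], [energy], [dynamics], [boundary].  Unknown
keys are errors, not warnings -- a silently misspelled cutoff is worse than
a crash.  Unset keys fall back to the packaged defaults (Table-style cutoff
and pair-list distances, dt = 10 fs, neighbor update every 20 steps).
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field

import numpy as np

from ..constants import (DEFAULT_CUTOFF, DEFAULT_DT, DEFAULT_FRICTION,
                         DEFAULT_NEIGHBOR_INTERVAL, DEFAULT_PAIRLIST)
from ..neighbor import BOX_RULE


class ControlError(ValueError):
    pass


_KEYS = {
    "input": {"top": str, "gro": str, "pwm": str, "charges": str},
    "output": {"dcd": str, "log": str, "traj_stride": int, "log_stride": int},
    "energy": {"temperature": float, "salt": float, "ionic_strength": float,
               "ele": bool, "intra_rna_ele": bool, "charge_scale": float,
               "pwm_gamma": float, "pwm_shift": float, "exv_eps": float,
               "cutoff_ele": float, "cutoff_hps": float, "cutoff_bp": float,
               "pairlist_ele": float, "pairlist_hps": float,
               "pairlist_bp": float, "pairlist_exv": float,
               "pairlist_pwmcos": float, "pairlist_hb": float},
    "dynamics": {"nsteps": int, "dt": float, "friction": float, "seed": int,
                 "neighbor_interval": int},
    "boundary": {"type": str, "box_x": float, "box_y": float, "box_z": float},
}


@dataclass
class ControlConfig:
    top: str = ""
    gro: str = ""
    pwm: str = ""
    charges: str = ""
    dcd: str = ""
    log: str = ""
    traj_stride: int = 1000
    log_stride: int = 1000
    temperature: float = 300.0
    salt: float = 0.15
    ionic_strength: float | None = None
    ele: bool = True
    intra_rna_ele: bool = False
    charge_scale: float = 1.0
    pwm_gamma: float = 1.0
    pwm_shift: float = 0.0
    exv_eps: float = 0.2
    cutoff: dict = field(default_factory=lambda: dict(DEFAULT_CUTOFF))
    pairlist: dict = field(default_factory=lambda: dict(DEFAULT_PAIRLIST))
    nsteps: int = 0
    dt: float = DEFAULT_DT
    friction: float = DEFAULT_FRICTION
    seed: int = 0
    neighbor_interval: int = DEFAULT_NEIGHBOR_INTERVAL
    boundary: str = "none"
    box: np.ndarray | None = None

    def validate(self) -> None:
        for term in ("ele", "hps", "bp"):
            if self.pairlist[term] <= self.cutoff[term]:
                raise ControlError(
                    f"pair-list distance for {term} "
                    f"({self.pairlist[term]} A) must exceed the cutoff "
                    f"({self.cutoff[term]} A)")
        if self.boundary == "periodic":
            if self.box is None:
                raise ControlError("periodic boundary requires box_x/y/z")
            r_max = max(self.pairlist.values())
            if np.any(self.box < 3.0 * r_max - 1e-9):
                raise ControlError(
                    f"periodic box {self.box.tolist()} A must measure at "
                    f"least {BOX_RULE} ({3 * r_max:.1f} A here)")
        elif self.boundary != "none":
            raise ControlError(f"unknown boundary type {self.boundary!r}")
        if self.dt <= 0 or self.nsteps < 0 or self.neighbor_interval < 1:
            raise ControlError("invalid dynamics settings")

    def options(self) -> dict:
        return {"ele": self.ele, "intra_rna_ele": self.intra_rna_ele,
                "charge_scale": self.charge_scale, "exv_eps": self.exv_eps,
                "cutoff": self.cutoff, "pairlist": self.pairlist}


def read_control(path) -> ControlConfig:
    cp = configparser.ConfigParser(inline_comment_prefixes=(";", "#"))
    with open(path) as fh:
        cp.read_file(fh, source=str(path))
    cfg = ControlConfig()
    for section in cp.sections():
        if section not in _KEYS:
            raise ControlError(f"{path}: unknown section [{section}]")
        for key, raw in cp.items(section):
            if key not in _KEYS[section]:
                raise ControlError(
                    f"{path}: unknown key {key!r} in [{section}]")
            typ = _KEYS[section][key]
            if typ is bool:
                val = cp.getboolean(section, key)
            else:
                val = typ(raw)
            if key.startswith("cutoff_"):
                cfg.cutoff[key[7:]] = val
            elif key.startswith("pairlist_"):
                cfg.pairlist[key[9:]] = val
            elif section == "boundary" and key == "type":
                cfg.boundary = val
            elif section == "boundary":
                if cfg.box is None:
                    cfg.box = np.full(3, np.nan)
                cfg.box["xyz".index(key[4:])] = val
            else:
                setattr(cfg, key, val)
    if cfg.box is not None and np.any(np.isnan(cfg.box)):
        raise ControlError(f"{path}: box_x, box_y and box_z must all be set")
    cfg.validate()
    return cfg
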