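"""GROMACS .gro coordinate files.

The on-disk standard is nanometers (positions, %8.3f) and nm/ps
(velocities, %8.4f); internally everything is A and A/fs.  An ``units``
flag selects an A dialect for interoperability with tools that expect
angstrom coordinates in the same fixed-column layout.
"""

from __future__ import annotations

import numpy as np

from ..topology import CGTopology, Frame

_NM = 0.1          # A -> nm
_NM_PS = 100.0     # A/fs -> nm/ps


def write_coordinates(path, frame: Frame, topology: CGTopology | None = None,
                      title="rescg coordinates", units="nm") -> None:
    if topology is not None:
        frame.check_against(topology)
    scale, vscale = (_NM, _NM_PS) if units == "nm" else (1.0, 1.0)
    pos = frame.positions * scale
    vel = None if frame.velocities is None else frame.velocities * vscale
    n = len(pos)
    with open(path, "w") as fh:
        fh.write(f"{title}, t= {frame.time:.3f}\n")
        fh.write(f"{n:5d}\n")
        for i in range(n):
            if topology is not None:
                resid = int(topology.particles.resid[i]) % 100000
                resname = str(topology.particles.residue[i])[:5]
                name = str(topology.particles.name[i])[:5]
            else:
                resid, resname, name = (i + 1) % 100000, "RES", "CG"
            line = (f"{resid:5d}{resname:<5s}{name:>5s}{(i + 1) % 100000:5d}"
                    f"{pos[i, 0]:8.3f}{pos[i, 1]:8.3f}{pos[i, 2]:8.3f}")
            if vel is not None:
                line += f"{vel[i, 0]:8.4f}{vel[i, 1]:8.4f}{vel[i, 2]:8.4f}"
            fh.write(line + "\n")
        if frame.box is not None:
            b = frame.box * scale
            fh.write(f"{b[0]:10.5f}{b[1]:10.5f}{b[2]:10.5f}\n")
        else:
            fh.write(f"{0.0:10.5f}{0.0:10.5f}{0.0:10.5f}\n")


def read_coordinates(path, units="nm") -> Frame:
    scale, vscale = (_NM, _NM_PS) if units == "nm" else (1.0, 1.0)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise ValueError(f"{path}: truncated .gro file")
    n = int(lines[1].split()[0])
    if len(lines) < n + 3:
        raise ValueError(f"{path}: expected {n} atom records")
    pos = np.empty((n, 3))
    vel = np.empty((n, 3))
    has_vel = len(lines[2].rstrip("\n")) >= 68
    for i in range(n):
        ln = lines[2 + i]
        pos[i] = [float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
        if has_vel:
            vel[i] = [float(ln[44:52]), float(ln[52:60]), float(ln[60:68])]
    box_vals = [float(x) for x in lines[2 + n].split()[:3]]
    box = None
    if any(v > 0 for v in box_vals):
        box = np.array(box_vals) / scale
    return Frame(positions=pos / scale,
                 velocities=vel / vscale if has_vel else None,
                 box=box)
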