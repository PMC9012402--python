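"""Binary DCD trajectory output/input (single precision, A).

Backed by mdtraj's low-level ``DCDTrajectoryFile``, which works in the
format's native angstrom units.  One coordinate set per frame; a unit-cell
record is included only for periodic frames.  The zero-frame edge case
(header only) is written explicitly so the file stays readable.
"""

from __future__ import annotations

import struct

import numpy as np
from mdtraj.formats import DCDTrajectoryFile

from ..topology import Frame


class DCDWriter:
    def __init__(self, path, n_atoms: int):
        self.path = str(path)
        self.n_atoms = int(n_atoms)
        self._fh = DCDTrajectoryFile(self.path, mode="w", force_overwrite=True)
        self.n_frames = 0

    def write(self, frame: Frame) -> None:
        pos = np.asarray(frame.positions, dtype=np.float32)
        if pos.shape != (self.n_atoms, 3):
            raise ValueError(
                f"frame has {pos.shape[0]} particles, writer expects "
                f"{self.n_atoms}")
        if frame.box is not None:
            self._fh.write(pos[None], cell_lengths=np.asarray(
                frame.box, dtype=np.float64)[None],
                cell_angles=np.array([[90.0, 90.0, 90.0]]))
        else:
            self._fh.write(pos[None])
        self.n_frames += 1

    def close(self) -> None:
        if self._fh is not None:
            self._fh.close()
            self._fh = None
        if self.n_frames == 0:
            _write_empty_dcd(self.path, self.n_atoms)
        else:
            _blank_title(self.path)

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def _blank_title(path) -> None:
    """Overwrite the free-text title lines with spaces so that identical
    runs produce byte-identical files (the backend stamps a creation time
    there)."""
    with open(path, "r+b") as fh:
        head_len = struct.unpack("<i", fh.read(4))[0]
        fh.seek(4 + head_len + 4)
        fh.read(4)  # title block length
        ntitle = struct.unpack("<i", fh.read(4))[0]
        if 0 < ntitle < 100:
            fh.write(b" " * (80 * ntitle))


def _write_empty_dcd(path, n_atoms: int) -> None:
    """Minimal valid CHARMM-style DCD header with zero frames."""
    with open(path, "wb") as fh:
        icntrl = [0] * 20
        icntrl[19] = 24  # CHARMM version tag
        head = b"CORD" + struct.pack("<20i", *icntrl)
        fh.write(struct.pack("<i", len(head)) + head
                 + struct.pack("<i", len(head)))
        title = b" " * 80
        tblock = struct.pack("<i", 1) + title
        fh.write(struct.pack("<i", len(tblock)) + tblock
                 + struct.pack("<i", len(tblock)))
        fh.write(struct.pack("<i", 4) + struct.pack("<i", n_atoms)
                 + struct.pack("<i", 4))


def write_dcd(frames, path) -> int:
    """Write a sequence of frames; returns the frame count."""
    frames = list(frames)
    n_atoms = len(frames[0].positions) if frames else 0
    with DCDWriter(path, n_atoms) as w:
        for f in frames:
            w.write(f)
        return w.n_frames


def read_dcd(path):
    """Read a DCD file -> (positions (n_frames, n, 3) A, boxes or None)."""
    with DCDTrajectoryFile(str(path)) as fh:
        xyz, cell_lengths, cell_angles = fh.read()
    boxes = None
    if cell_lengths is not None and len(cell_lengths):
        boxes = np.asarray(cell_lengths, dtype=float)
    return np.asarray(xyz, dtype=float), boxes
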