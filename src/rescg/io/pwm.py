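"""Plain-text position weight matrices.

Format: a header row of base letters giving the row order, then one row of
L numbers per base, and an optional trailing row starting with ``N`` giving
the per-column contact counts N_m (default 1):

    A C G T
    -0.5  1.2 ...
    ...
    N 4 4 4 ...
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..topology import BASE_CODES


@dataclass
class PWM:
    """4 x L score matrix in row order A, C, G, T plus per-column N_m."""
    scores: np.ndarray
    n_contacts: np.ndarray = field(default=None)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[0] != 4:
            raise ValueError("PWM must be 4 x L")
        if self.scores.shape[1] < 1:
            raise ValueError("PWM must have at least one column")
        if self.n_contacts is None:
            self.n_contacts = np.ones(self.scores.shape[1])
        self.n_contacts = np.asarray(self.n_contacts, dtype=float)
        if np.any(self.n_contacts < 1):
            raise ValueError("N_m must be >= 1")

    @property
    def length(self) -> int:
        return self.scores.shape[1]


def read_pwm(path) -> PWM:
    with open(path) as fh:
        lines = [ln.split() for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    header = [t.upper() for t in lines[0]]
    if sorted(header) != ["A", "C", "G", "T"]:
        raise ValueError(f"{path}: header must list the bases A C G T")
    rows = {}
    n_m = None
    for t in lines[1:]:
        if t[0].upper().startswith("N"):
            n_m = [float(x) for x in t[1:]]
        else:
            base = header[len(rows)]
            rows[base] = [float(x) for x in t]
    if len(rows) != 4:
        raise ValueError(f"{path}: expected 4 score rows")
    L = len(rows[header[0]])
    scores = np.empty((4, L))
    for base, vals in rows.items():
        if len(vals) != L:
            raise ValueError(f"{path}: ragged PWM rows")
        scores[BASE_CODES[base]] = vals
    return PWM(scores=scores, n_contacts=n_m)


def write_pwm(pwm: PWM, path) -> None:
    with open(path, "w") as fh:
        fh.write("A C G T\n")
        for r in range(4):
            fh.write(" ".join("%.17g" % v for v in pwm.scores[r]) + "\n")
        fh.write("N " + " ".join("%.17g" % v for v in pwm.n_contacts) + "\n")
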