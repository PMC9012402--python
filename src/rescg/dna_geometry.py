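"""Idealized B-DNA geometry: base-pair frames composed from base-step
parameters, and the P/S/B site / pseudo-atom templates used by the
sequence-to-structure builder.

Frame composition follows the mid-step-triad convention: for a step with
twist Omega, roll rho, tilt tau (rad) and displacement (shift, slide, rise)
(A), the bend magnitude is Gamma = sqrt(rho^2 + tau^2) at phase
phi = atan2(tau, rho), and

    R_step = Rz(Omega/2 - phi) . Ry(Gamma) . Rz(Omega/2 + phi)
    o_{i+1} = o_i + R_i . Rz(Omega/2 - phi) . Ry(Gamma/2) . Rz(phi) . d
    R_{i+1} = R_i . R_step

which for pure twist/rise reduces exactly to a helix with that twist and
rise.  The frame axes are x toward the major groove, y along the long
base-pair axis, z along the local helix axis.

The site template places the three CG sites per strand at B-DNA-like radii
(base ~3 A, sugar ~7 A, phosphate ~9 A from the axis); strand II positions
are the strand I template rotated by pi about x (y, z negated), which also
encodes the antiparallel backbone direction.
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# CG site template in the base-pair frame (strand I), A
SITE_TEMPLATE = {
    "B": np.array([1.0, -2.8, 0.0]),
    "S": np.array([-2.0, -6.8, 1.2]),
    "P": np.array([-3.5, -8.5, -1.0]),
}

_FLIP = np.diag([1.0, -1.0, -1.0])

# pseudo-atom offsets (A) around each site, with element symbols; group
# compositions approximate the heavy-atom content of the mapped groups
_PHOSPHATE_ATOMS = [("P", "P", (0.0, 0.0, 0.0)),
                    ("OP1", "O", (0.9, 0.6, 0.5)),
                    ("OP2", "O", (-0.9, 0.6, -0.5)),
                    ("O5'", "O", (0.3, -0.9, 0.6))]
_SUGAR_ATOMS = [("C1'", "C", (1.1, 0.4, -0.4)),
                ("C2'", "C", (1.0, -0.9, 0.3)),
                ("C3'", "C", (-0.2, -1.2, 0.5)),
                ("C4'", "C", (-1.1, -0.1, 0.2)),
                ("O4'", "O", (-0.1, 1.0, -0.3)),
                ("C5'", "C", (-0.9, 0.9, 0.8))]
_PURINE_ATOMS = [("N9", "N", (1.3, 0.9, 0.0)), ("C8", "C", (1.9, -0.3, 0.1)),
                 ("N7", "N", (1.1, -1.3, 0.1)), ("C5", "C", (-0.2, -0.8, 0.0)),
                 ("C4", "C", (0.0, 0.6, 0.0)), ("N3", "N", (-1.0, 1.4, -0.1)),
                 ("C2", "C", (-2.2, 0.8, -0.1)), ("N1", "N", (-2.4, -0.5, 0.0)),
                 ("C6", "C", (-1.4, -1.4, 0.0))]
_PYRIMIDINE_ATOMS = [("N1", "N", (1.2, 0.7, 0.0)), ("C2", "C", (1.2, -0.7, 0.1)),
                     ("N3", "N", (0.0, -1.4, 0.1)), ("C4", "C", (-1.2, -0.7, 0.0)),
                     ("C5", "C", (-1.2, 0.7, -0.1)), ("C6", "C", (0.0, 1.4, 0.0))]

PURINES = {"A", "G"}


def rotation_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def step_transform(twist, tilt, roll, shift, slide, rise):
    """(R_step, displacement in frame i) for one base-pair step.

    Angles in degrees, displacements in A.
    """
    om, ta, ro = np.radians([twist, tilt, roll])
    gamma = np.hypot(ro, ta)
    phi = np.arctan2(ta, ro) if gamma > 0 else 0.0
    r_step = rotation_z(om / 2 - phi) @ rotation_y(gamma) @ rotation_z(
        om / 2 + phi)
    r_mid = rotation_z(om / 2 - phi) @ rotation_y(gamma / 2) @ rotation_z(phi)
    disp = r_mid @ np.array([shift, slide, rise])
    return r_step, disp


def compose_frames(steps) -> tuple[np.ndarray, np.ndarray]:
    """Compose n frames from n-1 step parameter rows.

    ``steps`` iterates (twist, tilt, roll, shift, slide, rise) per
    dinucleotide step.  Returns (origins (n,3), rotations (n,3,3)).
    """
    origins = [np.zeros(3)]
    rots = [np.eye(3)]
    for row in steps:
        r_step, disp = step_transform(*row)
        origins.append(origins[-1] + rots[-1] @ disp)
        rots.append(rots[-1] @ r_step)
    return np.array(origins), np.array(rots)


def site_position(origin, rot, site: str, strand: int) -> np.ndarray:
    local = SITE_TEMPLATE[site]
    if strand == 1:
        local = _FLIP @ local
    return origin + rot @ local


def atoms_for(base: str, strand: int):
    """(atom name, element, local position) tuples for one nucleotide."""
    out = []
    ring = _PURINE_ATOMS if base in PURINES else _PYRIMIDINE_ATOMS
    for group, site in (( _PHOSPHATE_ATOMS, "P"), (_SUGAR_ATOMS, "S"),
                        (ring, "B")):
        anchor = SITE_TEMPLATE[site]
        for name, elem, off in group:
            local = anchor + np.asarray(off)
            if strand == 1:
                local = _FLIP @ local
            out.append((name, elem, local))
    return out


def reference_pair_geometry() -> dict:
    """Native Watson-Crick pair geometry implied by the site template:
    r0 = |B1 B2|, theta1/theta2 = sugar-base-base angles, phi0 = the
    S-B-B-S dihedral -- all in a single ideal base-pair frame."""
    b1 = SITE_TEMPLATE["B"]
    s1 = SITE_TEMPLATE["S"]
    b2 = _FLIP @ SITE_TEMPLATE["B"]
    s2 = _FLIP @ SITE_TEMPLATE["S"]

    def angle(a, b, c):
        u, v = a - b, c - b
        return float(np.arccos(np.clip(
            u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)))

    def dihedral(p1, p2, p3, p4):
        b1v, b2v, b3v = p2 - p1, p3 - p2, p4 - p3
        m = np.cross(b1v, b2v)
        n = np.cross(b2v, b3v)
        return float(np.arctan2(np.linalg.norm(b2v) * (b1v @ n), m @ n))

    return {"r0": float(np.linalg.norm(b2 - b1)),
            "theta1_0": angle(s1, b1, b2),
            "theta2_0": angle(b1, b2, s2),
            "phi0": dihedral(s1, b1, b2, s2)}


def reference_stack_geometry(twist=34.3, rise=3.32) -> dict:
    """Native intra-strand stacking geometry from an ideal uniform helix."""
    (o0, o1), (r0m, r1m) = compose_frames(
        [(twist, 0.0, 0.0, 0.0, 0.0, rise)])
    s0 = site_position(o0, r0m, "S", 0)
    b0 = site_position(o0, r0m, "B", 0)
    b1 = site_position(o1, r1m, "B", 0)
    u, v = s0 - b0, b1 - b0
    theta0 = float(np.arccos(np.clip(
        u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)))
    return {"r0": float(np.linalg.norm(b1 - b0)), "theta0": theta0}


def reference_cross_stack_geometry(twist=34.3, rise=3.32) -> dict:
    """Native cross-stacking geometry (base i of strand I against the 3'
    neighbor of its partner on strand II) from an ideal uniform helix."""
    (o0, o1), (r0m, r1m) = compose_frames(
        [(twist, 0.0, 0.0, 0.0, 0.0, rise)])
    # partner of bp 0 on strand II; its 3' neighbor along strand II runs
    # toward decreasing bp index, so the cross partner sits in bp frame 1
    # relative to base 0 of strand I when scanning 5'->3' on strand I.
    b_i = site_position(o0, r0m, "B", 0)
    s_i = site_position(o0, r0m, "S", 0)
    b_x = site_position(o1, r1m, "B", 1)
    s_x = site_position(o1, r1m, "S", 1)

    def angle(a, b, c):
        u, v = a - b, c - b
        return float(np.arccos(np.clip(
            u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)))

    return {"r0": float(np.linalg.norm(b_x - b_i)),
            "theta3_0": angle(s_i, b_i, b_x),
            "thetaCS_0": angle(b_i, b_x, s_x)}
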