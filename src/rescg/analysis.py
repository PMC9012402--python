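"""Trajectory observables: Rg, superposed RMSD, nativeness Q, slab density
profiles, droplet radial distributions, DNA-binding position, DNA bend
angle and wrapped-base-pair counts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .topology import CGTopology, Frame


@dataclass
class ProfileResult:
    """Binned profile: uniform bin centers plus values (units per op)."""
    centers: np.ndarray
    values: np.ndarray
    frame_range: tuple = (0, 0)

    def __post_init__(self):
        widths = np.diff(self.centers)
        if len(widths) and not np.allclose(widths, widths[0]):
            raise ValueError("bins must be uniform")


def _sel(frame, selection):
    pos = frame.positions if isinstance(frame, Frame) else np.asarray(frame)
    if selection is None:
        return pos
    return pos[np.asarray(selection, dtype=np.int64)]


def radius_of_gyration(frame, selection=None, masses=None) -> float:
    """Rg = sqrt(<m ||r - r_com||^2> / <m>) (unweighted when masses=None)."""
    pos = _sel(frame, selection)
    if len(pos) == 0:
        raise ValueError("empty selection")
    if masses is None:
        w = np.ones(len(pos))
    else:
        w = np.asarray(masses, dtype=float)
        if selection is not None and len(w) != len(pos):
            w = w[np.asarray(selection)]
    com = (pos * w[:, None]).sum(axis=0) / w.sum()
    d2 = np.sum((pos - com) ** 2, axis=1)
    return float(np.sqrt((w * d2).sum() / w.sum()))


def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid superposition (Kabsch); returns transformed mobile."""
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(rc, mc)
    return rot.apply(mc) + reference.mean(axis=0)


def rmsd(frame, reference, selection=None) -> float:
    """RMSD after least-squares rigid-body superposition, A."""
    a = _sel(frame, selection)
    b = _sel(reference, selection)
    if a.shape != b.shape:
        raise ValueError("selection size mismatch")
    a = superpose(a, b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def q_score(frame, contacts, factor: float = 1.2) -> float:
    """Fraction of native contacts formed: r_ij < factor * sigma_ij."""
    if len(contacts.idx) == 0:
        raise ValueError("empty contact list")
    pos = frame.positions if isinstance(frame, Frame) else np.asarray(frame)
    r = np.linalg.norm(pos[contacts.idx[:, 0]] - pos[contacts.idx[:, 1]],
                       axis=1)
    return float(np.mean(r < factor * contacts.sigma))


def density_profile_z(frames, box, bin_width: float = 10.0,
                      selection=None) -> ProfileResult:
    """Particle number density along z, particles/nm^3 (slab geometry).

    ``box`` is the orthorhombic box (A); positions are wrapped into it.
    """
    box = np.asarray(box, dtype=float)
    if box.shape != (3,):
        raise ValueError("need an orthorhombic box")
    nbin = max(int(round(box[2] / bin_width)), 1)
    edges = np.linspace(0.0, box[2], nbin + 1)
    counts = np.zeros(nbin)
    frames = list(frames) if not isinstance(frames, (list, tuple)) \
        else frames
    for fr in frames:
        z = _sel(fr, selection)[:, 2] % box[2]
        counts += np.histogram(z, bins=edges)[0]
    counts /= max(len(frames), 1)
    bin_vol_nm3 = box[0] * box[1] * (edges[1] - edges[0]) * 1e-3
    return ProfileResult(centers=0.5 * (edges[:-1] + edges[1:]),
                         values=counts / bin_vol_nm3,
                         frame_range=(0, len(frames)))


def rdf_from_com(frames, selection_a, selection_b,
                 bin_width: float = 5.0, r_max: float = 200.0
                 ) -> ProfileResult:
    """Shell-normalized density of B particles versus distance from the
    center of mass of selection A (droplet geometry), particles/nm^3."""
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    frames = list(frames) if not isinstance(frames, (list, tuple)) \
        else frames
    for fr in frames:
        a = _sel(fr, selection_a)
        b = _sel(fr, selection_b)
        if len(a) == 0:
            raise ValueError("empty droplet selection")
        com = a.mean(axis=0)
        r = np.linalg.norm(b - com, axis=1)
        counts += np.histogram(r, bins=edges)[0]
    counts /= max(len(frames), 1)
    shell_vol_nm3 = (4.0 / 3.0) * np.pi * np.diff(edges ** 3) * 1e-3
    return ProfileResult(centers=0.5 * (edges[:-1] + edges[1:]),
                         values=counts / shell_vol_nm3,
                         frame_range=(0, len(frames)))


def _bp_centers(frame, topology: CGTopology) -> np.ndarray:
    """Base-pair center positions of a duplex, ordered along strand I."""
    bp = topology.basepairs
    if bp is None:
        raise ValueError("topology has no DNA base records")
    P = topology.particles
    pos = frame.positions if isinstance(frame, Frame) else np.asarray(frame)
    chains = sorted({P.chain[i] for i in bp.base_idx})
    if len(chains) != 2:
        raise ValueError("need a two-strand duplex")
    s1 = [int(b) for b in bp.base_idx if P.chain[b] == chains[0]]
    s2 = [int(b) for b in bp.base_idx if P.chain[b] == chains[1]]
    if len(s1) != len(s2):
        raise ValueError("strand length mismatch")
    s2 = s2[::-1]  # antiparallel register
    k1 = [int(np.where(bp.base_idx == b)[0][0]) for b in s1]
    k2 = [int(np.where(bp.base_idx == b)[0][0]) for b in s2]
    base_mid = 0.5 * (pos[s1] + pos[s2])
    sugar_mid = 0.5 * (pos[bp.sugar_idx[k1]] + pos[bp.sugar_idx[k2]])
    # 2:1 base:sugar weighting cancels most of the helical wobble of the
    # raw base midpoints, leaving a near-axial center per pair
    return (2.0 * base_mid + sugar_mid) / 3.0


def dna_binding_position(frame, protein_selection, topology: CGTopology,
                         masses=None) -> int:
    """Base-pair index (0-based along strand I) nearest the protein COM;
    ties break to the lower index."""
    pos = frame.positions if isinstance(frame, Frame) else np.asarray(frame)
    psel = np.asarray(protein_selection)
    w = (np.ones(len(psel)) if masses is None
         else np.asarray(masses, dtype=float))
    com = (pos[psel] * w[:, None]).sum(axis=0) / w.sum()
    centers = _bp_centers(frame, topology)
    d = np.linalg.norm(centers - com, axis=1)
    return int(np.argmin(d))     # argmin takes the first (lowest) index


def dna_bend_angle(frame, topology: CGTopology, end_window: int = 10
                   ) -> float:
    """Angle (degrees) between the helical-axis directions of the two duplex
    ends, each fit by least squares over ``end_window`` base-pair centers."""
    centers = _bp_centers(frame, topology)
    if len(centers) <= 2 * end_window:
        raise ValueError("duplex shorter than twice the end window")

    def axis(pts):
        c = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(c)
        v = vt[0]
        # orient 5'->3' along the window
        if v @ (pts[-1] - pts[0]) < 0:
            v = -v
        return v

    v1 = axis(centers[:end_window])
    v2 = axis(centers[-end_window:])
    return float(np.degrees(np.arccos(np.clip(v1 @ v2, -1.0, 1.0))))


def wrapped_bp_count(frame, topology: CGTopology, core_selection,
                     criterion: float = 10.0) -> int:
    """Number of base pairs with at least one CG site within ``criterion``
    (A) of any core (histone) particle."""
    if criterion <= 0:
        return 0
    from scipy.spatial import cKDTree
    pos = frame.positions if isinstance(frame, Frame) else np.asarray(frame)
    core = np.asarray(core_selection)
    if len(core) == 0:
        return 0
    bp = topology.basepairs
    P = topology.particles
    chains = sorted({P.chain[i] for i in bp.base_idx})
    s1 = [(k, int(b)) for k, b in enumerate(bp.base_idx)
          if P.chain[b] == chains[0]]
    s2 = [(k, int(b)) for k, b in enumerate(bp.base_idx)
          if P.chain[b] == chains[1]]
    s2 = s2[::-1]
    tree = cKDTree(pos[core])
    count = 0
    dna_sites_of = {}
    # all sites of each nucleotide: base + its sugar (+ phosphate if any)
    for (k1, b1), (k2, b2) in zip(s1, s2):
        sites = [b1, int(bp.sugar_idx[k1]), b2, int(bp.sugar_idx[k2])]
        d, _ = tree.query(pos[sites], k=1)
        if np.min(d) < criterion:
            count += 1
    return count
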