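"""Cell-linked-list neighbor lists, one per nonbonded interaction term.

The box is divided into cells once per rebuild; each term keeps its own
particle subset ("particle list") per cell and its own neighboring-cell
stencil derived from the minimum inter-cell distance criterion

    C_neighbor(term)(Ci) = {Ck : r_min(Ci, Ck) < r_P(term)}

so short-range terms (excluded volume, r_P = 15 A) scan far fewer cells than
long-range ones (electrostatics, r_P = 57 A).  Candidate pairs are stored once
with i < j, are within r_P at build time, and never contain excluded pairs.

Periodic boxes must measure at least three times the largest pair-list
distance per axis; non-periodic systems are gridded over their instantaneous
bounding box plus one margin cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K

BOX_RULE = "three times the largest pair-list distance"


class BoxTooSmallError(ValueError):
    pass


def check_box(box, pairlist_distances) -> None:
    """Enforce the periodic-box rule: each dimension >= 3 * max r_P."""
    r_max = max(pairlist_distances.values())
    box = np.asarray(box, dtype=float)
    if np.any(box < 3.0 * r_max - 1e-9):
        raise BoxTooSmallError(
            f"periodic box {box.tolist()} A violates the requirement of "
            f"{BOX_RULE} ({3 * r_max:.1f} A for r_P = {r_max:.1f} A)")


def _stencil(edge: np.ndarray, r_p: float, ncell: np.ndarray,
             pbc: bool) -> np.ndarray:
    """Integer cell offsets whose minimum inter-cell distance is < r_p.

    Periodic axes enumerate one full residue window (no image aliasing) and
    apply the wrapped inter-cell gap; open axes clip at the grid border.
    """
    lo = np.empty(3, int)
    hi = np.empty(3, int)
    for a in range(3):
        if pbc:
            lo[a] = -(ncell[a] // 2)
            hi[a] = (ncell[a] - 1) // 2
        else:
            reach = min(int(np.ceil(r_p / edge[a])) + 1, ncell[a] - 1)
            lo[a], hi[a] = -reach, reach
    offs = []
    for ox in range(lo[0], hi[0] + 1):
        for oy in range(lo[1], hi[1] + 1):
            for oz in range(lo[2], hi[2] + 1):
                d2 = 0.0
                for o, e, nc in ((ox, edge[0], ncell[0]),
                                 (oy, edge[1], ncell[1]),
                                 (oz, edge[2], ncell[2])):
                    oe = min(abs(o), nc - abs(o)) if pbc else abs(o)
                    gap = max(oe - 1, 0) * e
                    d2 += gap * gap
                if d2 < r_p * r_p:
                    offs.append((ox, oy, oz))
    return np.array(offs, dtype=np.int64)


@dataclass
class _SubsetBins:
    members: np.ndarray
    cell_order: np.ndarray
    cell_start: np.ndarray


@dataclass
class CellGrid:
    """Cell decomposition of one frame for a set of terms."""
    origin: np.ndarray
    edge: np.ndarray
    ncell: np.ndarray
    pbc: bool
    box: np.ndarray
    stencils: dict = field(default_factory=dict)    # term -> offsets
    neighbor_cells: dict = field(default_factory=dict)  # term -> cell table
    bins: dict = field(default_factory=dict)        # subset key -> _SubsetBins

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.ncell))


def build_grid(positions, pairlist_distances: dict, box=None,
               subsets: dict | None = None) -> CellGrid:
    """Divide the system into cells and bin each term's particle subset.

    Parameters
    ----------
    positions : (N, 3) array
    pairlist_distances : dict term -> r_P (A)
    box : optional orthorhombic box lengths; enables periodic wrapping and
        must satisfy the 3 * max(r_P) rule.
    subsets : dict key -> index array.  Each term's stencil is built here;
        pair construction happens in :func:`build_pairs`.
    """
    positions = np.asarray(positions, dtype=float)
    if not pairlist_distances:
        raise ValueError("need at least one pair-list distance")
    r_min_term = min(pairlist_distances.values())
    pbc = box is not None
    # cells of about half the shortest pair-list distance: the per-term
    # stencils then hug the r_min < r_P sphere much more tightly than
    # r_P-sized cells would, which is what makes the candidate scan cheap
    target = 0.5 * r_min_term
    if pbc:
        check_box(box, pairlist_distances)
        box = np.asarray(box, dtype=float)
        origin = np.zeros(3)
        ncell = np.maximum(np.floor(box / target).astype(int), 3)
        edge = box / ncell
    else:
        if len(positions):
            lo = positions.min(axis=0)
            hi = positions.max(axis=0)
        else:
            lo = np.zeros(3)
            hi = np.ones(3)
        span = np.maximum(hi - lo, 1e-6)
        ncell = np.maximum(np.ceil(span / target).astype(int), 1) + 2
        edge = np.maximum(span / np.maximum(ncell - 2, 1), 1e-6)
        origin = lo - edge
        box = np.array([1.0, 1.0, 1.0])  # unused
    grid = CellGrid(origin=origin, edge=edge, ncell=ncell, pbc=pbc, box=box)
    for term, r_p in pairlist_distances.items():
        offs = _stencil(edge, r_p, ncell, pbc)
        grid.stencils[term] = offs
        grid.neighbor_cells[term] = _resolve_cells(offs, ncell, pbc)
    for key, subset in (subsets or {}).items():
        bin_subset(grid, positions, key, subset)
    return grid


def _resolve_cells(offsets, ncell, pbc) -> np.ndarray:
    """(n_cells, n_offsets) table of neighboring-cell ids (-1 outside an
    open boundary), resolved once so the pair scan does no index math."""
    nx, ny, nz = (int(v) for v in ncell)
    cx, cy, cz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    cells = np.stack([cx.ravel(), cy.ravel(), cz.ravel()], axis=1)
    n_cells = cells.shape[0]
    out = np.empty((n_cells, len(offsets)), dtype=np.int64)
    for m, (ox, oy, oz) in enumerate(offsets):
        tx = cells[:, 0] + ox
        ty = cells[:, 1] + oy
        tz = cells[:, 2] + oz
        if pbc:
            tx %= nx
            ty %= ny
            tz %= nz
            out[:, m] = (tx * ny + ty) * nz + tz
        else:
            ok = ((tx >= 0) & (tx < nx) & (ty >= 0) & (ty < ny)
                  & (tz >= 0) & (tz < nz))
            out[:, m] = np.where(ok, (tx * ny + ty) * nz + tz, -1)
    return out


def bin_subset(grid: CellGrid, positions, key, subset) -> None:
    subset = np.ascontiguousarray(subset, dtype=np.int64)
    if subset.size == 0:
        grid.bins[key] = _SubsetBins(subset, np.empty(0, np.int64),
                                     np.zeros(grid.n_cells + 1, np.int64))
        return
    cells = K.bin_particles(positions, subset, grid.origin, grid.edge,
                            grid.ncell, grid.pbc)
    order = np.argsort(cells, kind="stable")
    counts = np.bincount(cells, minlength=grid.n_cells)
    start = np.zeros(grid.n_cells + 1, dtype=np.int64)
    np.cumsum(counts, out=start[1:])
    grid.bins[key] = _SubsetBins(subset, order, start)


_EMPTY_EXCL = np.empty(0, dtype=np.int64)


def exclusion_keys(exclusions, n_particles: int) -> np.ndarray:
    """Sorted i*N+j keys (i<j) for the compiled binary-search filter."""
    if exclusions is None or len(exclusions) == 0:
        return _EMPTY_EXCL
    arr = np.asarray(sorted(
        min(i, j) * n_particles + max(i, j) for i, j in exclusions),
        dtype=np.int64)
    return arr


def build_pairs(grid: CellGrid, positions, term: str, r_p: float,
                subset_a="all", subset_b=None, excl_keys=_EMPTY_EXCL,
                n_particles: int | None = None,
                capacity_hint: int = 0) -> np.ndarray:
    """Candidate pairs for one term: all (i, j), i < j, with r_ij < r_P and
    (i, j) not excluded.  ``subset_b`` switches to cross-subset pairing."""
    positions = np.asarray(positions, dtype=float)
    if n_particles is None:
        n_particles = len(positions)
    neigh = grid.neighbor_cells[term]
    ba = grid.bins[subset_a]
    if ba.members.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    if subset_b is not None:
        bb = grid.bins[subset_b]
        if bb.members.size == 0:
            return np.empty((0, 2), dtype=np.int64)
    cap = max(int(capacity_hint), 4096)
    while True:
        out = np.empty((cap, 2), dtype=np.int64)
        if subset_b is None:
            n = K.build_pairs_same(
                positions, ba.members, ba.cell_start, ba.cell_order, neigh,
                r_p, n_particles, excl_keys, grid.box, grid.pbc, out)
        else:
            n = K.build_pairs_cross(
                positions, ba.members, ba.cell_start, ba.cell_order,
                bb.members, bb.cell_start, bb.cell_order, neigh,
                r_p, n_particles, excl_keys, grid.box, grid.pbc, out)
        if n >= 0:
            return np.ascontiguousarray(out[:n])
        cap *= 4


@dataclass
class NeighborLists:
    """Per-term candidate pair arrays (plus precomputed per-pair parameters)
    and rebuild bookkeeping."""
    pairs: dict
    build_positions: np.ndarray
    steps_since_build: int = 0
    params: dict = field(default_factory=dict)

    def __getitem__(self, term):
        return self.pairs[term]


class NeighborState:
    """Owns the grid/list lifecycle during a run (20-step cadence default)."""

    def __init__(self, system, interval: int = 20):
        self.system = system
        self.interval = int(interval)
        self.lists: NeighborLists | None = None

    def maybe_rebuild(self, positions, box=None) -> NeighborLists:
        """Rebuild iff the lists have aged ``interval`` steps (or never built)."""
        if self.lists is None:
            self.lists = self.system.build_neighbor_lists(positions, box)
        else:
            self.lists.steps_since_build += 1
            if self.lists.steps_since_build >= self.interval:
                self.lists = self.system.build_neighbor_lists(positions, box)
        return self.lists
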