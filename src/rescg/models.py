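"""Assembly of the basic terms into full model energy functions.

A :class:`CGSystem` wraps a validated :class:`~rescg.topology.CGTopology`
plus run options (electrostatic environment, cutoffs, optional terms) and
evaluates the total potential energy and its exact analytic gradient for a
frame, split per interaction term.  The supported models are:

- AICG2+ (folded proteins): harmonic bonds, tabulated angles, 1-3 Gaussians,
  Gaussian + tabulated dihedrals, Go contacts, r^-12 excluded volume.
- HPS / KH (disordered regions, one-bead RNA): harmonic bonds,
  Debye-Hueckel electrostatics, Ashbaugh-Hatch pair term.
- 3SPN.2C (DNA): quartic bonds, harmonic angles, periodic + Gaussian
  dihedrals, base stacking / Watson-Crick pairing / cross stacking,
  phosphate electrostatics, truncated-LJ excluded volume.
- Structure-based RNA: harmonic bonds/angles, periodic dihedrals, Go
  contacts, excluded volume, optional intra-RNA electrostatics.
- PWMcos and the backbone-HB variant for protein-DNA interfaces.

Cross-molecule interactions follow the model-combination matrix: excluded
volume always, electrostatics / Go / PWMcos / HB as options; disallowed
combinations raise at construction rather than being silently filtered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from . import neighbor as nb
from .constants import COULOMB, DEFAULT_CUTOFF, DEFAULT_PAIRLIST
from .potentials import ElectrostaticEnvironment, SplineTable
from .topology import CGTopology, Frame

TERM_NAMES = ("bond", "angle", "dihedral", "contact_go", "gauss13", "exv",
              "ele", "hps", "base_stack", "base_pair", "cross_stack",
              "pwmcos", "hb")

_DUMMY_BOX = np.array([1.0, 1.0, 1.0])
_DUMMY_I = np.empty(0, dtype=np.int64)


class CombinationError(ValueError):
    """A model combination outside the supported matrix was requested."""


@dataclass
class Exclusions:
    """Nonbonded exclusion sets: ``nonbonded`` applies to every generic
    pair term; ``exv`` additionally removes native contacts and DNA
    stacking / Watson-Crick partners from the excluded-volume term."""
    nonbonded: set
    exv: set


def build_exclusions(topology: CGTopology) -> Exclusions:
    nbx = topology.bonded_exclusions()
    return Exclusions(nonbonded=nbx, exv=topology.exv_exclusions())


@dataclass
class EnergyReport:
    """Per-term energies (kcal/mol), their total, and forces (kcal/mol/A)."""
    terms: dict
    forces: np.ndarray

    @property
    def total(self) -> float:
        return float(sum(self.terms.values()))

    def __getitem__(self, key):
        return self.terms[key]

    def summary(self) -> str:
        lines = [f"{k:>12s} {v: .6f}" for k, v in self.terms.items()]
        lines.append(f"{'total':>12s} {self.total: .6f}")
        return "\n".join(lines)


class _TableBank:
    """Flat spline-coefficient arrays consumable by the compiled kernels."""

    def __init__(self, tables: dict[str, SplineTable], names):
        self.index = {}
        x0, dx, nseg, seg0, lo, hi = [], [], [], [], [], []
        breaks, coefs = [], []
        off = 0
        for name in names:
            if name in self.index or not name:
                continue
            t = tables[name]
            bx, c = t.coefficients()
            self.index[name] = len(x0)
            x0.append(bx[0])
            dx.append(bx[1] - bx[0])
            nseg.append(c.shape[1])
            seg0.append(off)
            lo.append(bx[0])
            hi.append(bx[-1])
            breaks.append(bx[:-1])
            coefs.append(c)
            off += c.shape[1]
        if x0:
            self.x0 = np.array(x0)
            self.dx = np.array(dx)
            self.nseg = np.array(nseg, dtype=np.int64)
            self.seg0 = np.array(seg0, dtype=np.int64)
            self.lo = np.array(lo)
            self.hi = np.array(hi)
            self.breaks = np.concatenate(breaks)
            self.coefs = np.concatenate(coefs, axis=1)
        else:
            self.x0 = self.dx = self.lo = self.hi = np.zeros(1)
            self.nseg = self.seg0 = np.zeros(1, dtype=np.int64)
            self.breaks = np.zeros(1)
            self.coefs = np.zeros((4, 1))

    def ids(self, names) -> np.ndarray:
        return np.array([self.index.get(n, -1) for n in names],
                        dtype=np.int64)


def validate_combination(topology: CGTopology, options: dict) -> None:
    """Reject model combinations outside the supported matrix."""
    classes = set(topology.particles.mol_class)
    if topology.pwmcos is not None or topology.hbsites is not None:
        if "dna" not in classes or "protein" not in classes:
            raise CombinationError(
                "PWMcos/HB terms require both protein and DNA molecules")
    if topology.basepairs is not None and "dna" not in classes:
        raise CombinationError("base-pair records require DNA particles")
    hps_active = topology.particles.eps > 0
    if options.get("hps_dna", False) or (
            np.any(hps_active & (topology.particles.mol_class == "dna"))):
        raise CombinationError(
            "the Ashbaugh-Hatch pair model is not available for DNA")


class CGSystem:
    """One simulatable system: topology + parameters + run options.

    Parameters
    ----------
    topology : CGTopology
    env : ElectrostaticEnvironment, optional
        Required when electrostatics is enabled and charges exist.
    tables : dict, optional
        name -> :class:`SplineTable` for tabulated angle/dihedral records.
    pwm : PWM, optional
        Required when the topology carries PWMcos sites.
    pwm_gamma, pwm_shift : float
        Scale gamma and shift eps' of the PWM-to-energy map.
    options : dict, optional
        ``ele`` (default True), ``intra_rna_ele`` (default False),
        ``cutoff``/``pairlist`` per-term overrides (dict),
        ``charge_scale`` applied to all charges in the electrostatic term.
    """

    def __init__(self, topology: CGTopology, *, env=None, tables=None,
                 pwm=None, pwm_gamma=1.0, pwm_shift=0.0, options=None):
        topology.validate()
        self.topology = topology
        self.options = dict(options or {})
        validate_combination(topology, self.options)
        self.env = env or ElectrostaticEnvironment()
        self.pwm = pwm
        self.pwm_gamma = float(pwm_gamma)
        self.pwm_shift = float(pwm_shift)
        self.cutoff = dict(DEFAULT_CUTOFF)
        self.cutoff.update(self.options.get("cutoff", {}))
        self.pairlist = dict(DEFAULT_PAIRLIST)
        self.pairlist.update(self.options.get("pairlist", {}))

        P = topology.particles
        n = topology.n_particles
        self.n_particles = n
        self.ele_enabled = bool(self.options.get("ele", True))
        self.charge_scale = float(self.options.get("charge_scale", 1.0))
        self.hps_active = np.ascontiguousarray(P.eps > 0)
        self.charges = np.ascontiguousarray(P.charge * self.charge_scale)
        self.is_dna_site = np.ascontiguousarray(P.mol_class == "dna")
        self.exv_radius = np.ascontiguousarray(P.radius, dtype=float)
        eps_exv = self.options.get("exv_eps", 0.2)
        self.exv_eps = np.full(n, eps_exv, dtype=float)
        excl = build_exclusions(topology)
        self.excl_nb_keys = nb.exclusion_keys(excl.nonbonded, n)
        self.excl_exv_keys = nb.exclusion_keys(excl.exv, n)
        # base pairing scans all bases except bonded/stacked neighbors --
        # native WC partners must of course stay in
        self.excl_bp = set(excl.nonbonded)
        if topology.stacks is not None:
            for s, b5, b3 in topology.stacks.idx:
                self.excl_bp.add((min(b5, b3), max(b5, b3)))
        self.excl_bp_keys = nb.exclusion_keys(self.excl_bp, n)
        self.exclusions = excl

        # term subsets
        self.subset_all = np.arange(n, dtype=np.int64)
        self.subset_exv = self.subset_all[self.exv_radius > 0]
        self.subset_charged = self.subset_all[self.charges != 0.0]
        self.subset_hps = self.subset_all[self.hps_active]
        bpd = topology.basepairs
        self.subset_bases = (np.ascontiguousarray(bpd.base_idx, np.int64)
                             if bpd is not None else _DUMMY_I)
        pw = topology.pwmcos
        self.subset_pwm_ca = (np.unique(pw.ca_idx).astype(np.int64)
                              if pw is not None else _DUMMY_I)

        # table bank
        names = list(topology.angles.table) + list(topology.dihedrals.table)
        self.tables = dict(tables or {})
        self.bank = _TableBank(self.tables, names)
        self.angle_tab_ids = self.bank.ids(topology.angles.table)
        self.dihedral_tab_ids = self.bank.ids(topology.dihedrals.table)
        missing_a = (self.angle_tab_ids < 0) & (topology.angles.func == 21)
        missing_d = (self.dihedral_tab_ids < 0) & (topology.dihedrals.func == 22)
        if np.any(missing_a) or np.any(missing_d):
            raise ValueError("tabulated angle/dihedral records reference "
                             "missing tables")
        self.clamp_counter = np.zeros(1, dtype=np.int64)

        # static per-term arrays (contiguous copies for the kernels)
        self._prepare_static()

        # list-capacity hints (previous pair counts), cached periodic grid
        # geometry, and pwmcos site map
        self._cap: dict[str, int] = {}
        self._grid_cache = None
        self._ca_to_sites: dict[int, np.ndarray] = {}
        if pw is not None:
            if self.pwm is None:
                raise ValueError("topology has PWMcos sites but no PWM given")
            for s, ca in enumerate(pw.ca_idx):
                self._ca_to_sites.setdefault(int(ca), []).append(s)
            self._ca_to_sites = {k: np.array(v, dtype=np.int64)
                                 for k, v in self._ca_to_sites.items()}

    # ------------------------------------------------------------------
    def _prepare_static(self):
        t = self.topology

        def C(x, dtype=float):
            return np.ascontiguousarray(x, dtype=dtype)

        self._bonds = (C(t.bonds.idx, np.int64), C(t.bonds.func, np.int64),
                       C(t.bonds.b0), C(t.bonds.k1), C(t.bonds.k2))
        self._angles = (C(t.angles.idx, np.int64), C(t.angles.func, np.int64),
                        C(t.angles.theta0), C(t.angles.k))
        self._dihedrals = (C(t.dihedrals.idx, np.int64),
                           C(t.dihedrals.func, np.int64),
                           C(t.dihedrals.phi0), C(t.dihedrals.mult, np.int64),
                           C(t.dihedrals.k), C(t.dihedrals.sigma))
        self._contacts = (C(t.contacts.idx, np.int64), C(t.contacts.sigma),
                          C(t.contacts.eps))
        self._gauss13 = (C(t.gauss13.idx, np.int64), C(t.gauss13.r0),
                         C(t.gauss13.eps), C(t.gauss13.w))
        P = t.particles
        self._hps_sig = C(P.sigma)
        self._hps_lam = C(P.lam)
        self._hps_eps = C(P.eps)
        if t.stacks is not None:
            s = t.stacks
            self._stacks = (C(s.idx, np.int64), C(s.eps), C(s.alpha),
                            C(s.r0), C(s.theta0), C(s.gamma))
        if t.basepairs is not None:
            b = t.basepairs
            n = self.n_particles
            sugar_of = np.full(n, -1, dtype=np.int64)
            base3_of = np.full(n, -1, dtype=np.int64)
            base5_of = np.full(n, -1, dtype=np.int64)
            code_of = np.full(n, -1, dtype=np.int64)
            sugar_of[b.base_idx] = b.sugar_idx
            base3_of[b.base_idx] = b.base3
            base5_of[b.base_idx] = b.base5
            code_of[b.base_idx] = b.code
            self._bp_maps = (sugar_of, base5_of, base3_of, code_of)
            pp = b.pair_params
            self._wc = tuple(
                np.array([pp["AT"][f], pp["GC"][f]])
                for f in ("eps", "alpha", "r0", "theta1_0", "theta2_0",
                          "phi0", "gamma"))
            cp = b.cstk_params
            self._cs = tuple(
                np.array([cp["AT"][f], cp["GC"][f]])
                for f in ("eps", "alpha", "r0", "theta3_0", "thetaCS_0",
                          "gamma"))
        if t.pwmcos is not None:
            p = t.pwmcos
            self._pwm_sites = (C(p.ca_idx, np.int64), C(p.ca_prev, np.int64),
                               C(p.ca_next, np.int64), C(p.col, np.int64),
                               C(p.strand, np.int64), C(p.r0), C(p.theta1_0),
                               C(p.theta2_0), C(p.theta3_0), C(p.w),
                               C(p.gamma))
        if t.hbsites is not None:
            h = t.hbsites
            self._hb = (C(h.p_idx, np.int64), C(h.s_idx, np.int64),
                        C(h.ca_idx, np.int64), C(h.ca_prev, np.int64),
                        C(h.ca_next, np.int64), C(h.r0), C(h.theta1_0),
                        C(h.theta2_0), C(h.eps), C(h.w), C(h.gamma))

    # ------------------------------------------------------------------
    # neighbor lists
    # ------------------------------------------------------------------
    def active_pair_terms(self):
        terms = []
        if (self.subset_exv.size > 1
                and not np.all(self.hps_active[self.subset_exv])):
            terms.append("exv")
        if self.ele_enabled and self.subset_charged.size > 1:
            terms.append("ele")
        if self.subset_hps.size > 1:
            terms.append("hps")
        if self.topology.basepairs is not None and self.subset_bases.size > 1:
            terms.append("bp")
        if self.topology.pwmcos is not None and self.subset_pwm_ca.size:
            terms.append("pwmcos")
        return terms

    def build_neighbor_lists(self, positions, box=None) -> nb.NeighborLists:
        terms = self.active_pair_terms()
        positions = np.ascontiguousarray(positions, dtype=float)
        pairs = {}
        if terms:
            rp = {t: self.pairlist[t] for t in terms}
            needed = {}
            for term in terms:
                if term == "bp":
                    needed["bases"] = self.subset_bases
                elif term == "pwmcos":
                    needed["bases"] = self.subset_bases
                    needed["pwm_ca"] = self.subset_pwm_ca
                elif term == "exv":
                    needed["exv"] = self.subset_exv
                elif term == "ele":
                    needed["ele"] = self.subset_charged
                elif term == "hps":
                    needed["hps"] = self.subset_hps
            if (box is not None and self._grid_cache is not None
                    and self._grid_cache[0] == (tuple(np.asarray(box)),
                                                tuple(sorted(rp)))):
                grid = self._grid_cache[1]
                for key, subset in needed.items():
                    nb.bin_subset(grid, positions, key, subset)
            else:
                grid = nb.build_grid(positions, rp, box=box, subsets=needed)
                if box is not None:
                    self._grid_cache = ((tuple(np.asarray(box)),
                                         tuple(sorted(rp))), grid)
            for term in terms:
                hint = int(1.5 * self._cap.get(term, 0))
                if term == "bp":
                    pairs["bp"] = nb.build_pairs(
                        grid, positions, "bp", self.pairlist["bp"],
                        subset_a="bases", excl_keys=self.excl_bp_keys,
                        n_particles=self.n_particles, capacity_hint=hint)
                elif term == "pwmcos":
                    raw = nb.build_pairs(
                        grid, positions, "pwmcos", self.pairlist["pwmcos"],
                        subset_a="bases", subset_b="pwm_ca",
                        n_particles=self.n_particles, capacity_hint=hint)
                    pairs["pwmcos"] = self._expand_pwm_pairs(raw)
                else:
                    keys = (self.excl_exv_keys if term == "exv"
                            else self.excl_nb_keys)
                    pairs[term] = nb.build_pairs(
                        grid, positions, term, self.pairlist[term],
                        subset_a=term, excl_keys=keys,
                        n_particles=self.n_particles, capacity_hint=hint)
                self._cap[term] = (len(raw) if term == "pwmcos"
                                   else len(pairs[term]))
            if "ele" in pairs:
                pairs["ele"] = self._filter_intra_rna(pairs["ele"])
        lists = nb.NeighborLists(pairs=pairs,
                                 build_positions=positions.copy())
        self._attach_pair_params(lists)
        return lists

    def brute_force_lists(self, positions) -> nb.NeighborLists:
        """All-pairs candidate lists (no grid) -- the O(N^2) oracle path."""
        pairs = {}

        def allpairs(sub_a, sub_b, excl):
            out = []
            if sub_b is None:
                for ii in range(len(sub_a)):
                    for jj in range(ii + 1, len(sub_a)):
                        i, j = int(sub_a[ii]), int(sub_a[jj])
                        a, b = (i, j) if i < j else (j, i)
                        if (a, b) not in excl:
                            out.append((a, b))
            else:
                for i in sub_a:
                    for j in sub_b:
                        a, b = (int(i), int(j)) if i < j else (int(j), int(i))
                        if (a, b) not in excl:
                            out.append((int(i), int(j)))
            return (np.array(out, dtype=np.int64) if out
                    else np.empty((0, 2), dtype=np.int64))

        for term in self.active_pair_terms():
            if term == "exv":
                pairs["exv"] = allpairs(self.subset_exv, None,
                                        self.exclusions.exv)
            elif term == "ele":
                pairs["ele"] = self._filter_intra_rna(
                    allpairs(self.subset_charged, None,
                             self.exclusions.nonbonded))
            elif term == "hps":
                pairs["hps"] = allpairs(self.subset_hps, None,
                                        self.exclusions.nonbonded)
            elif term == "bp":
                pairs["bp"] = allpairs(self.subset_bases, None,
                                       self.excl_bp)
            elif term == "pwmcos":
                raw = allpairs(self.subset_bases, self.subset_pwm_ca, set())
                # store as (base, ca) ordering regardless of index order
                if raw.size:
                    in_bases = np.isin(raw[:, 0], self.subset_bases)
                    raw = np.where(in_bases[:, None], raw, raw[:, ::-1])
                pairs["pwmcos"] = self._expand_pwm_pairs(raw)
        lists = nb.NeighborLists(pairs=pairs,
                                 build_positions=np.asarray(positions, float))
        self._attach_pair_params(lists)
        return lists

    def _attach_pair_params(self, lists):
        """Precompute per-pair parameters once per rebuild (combination
        rules applied here, not in the per-step kernels)."""
        p = lists.pairs
        # i-major order rewards the force kernels with cache locality
        for term in ("exv", "hps"):
            if term in p and len(p[term]) > 1:
                order = np.argsort(p[term][:, 0], kind="stable")
                p[term] = np.ascontiguousarray(p[term][order])
        if "exv" in p and len(p["exv"]):
            i, j = p["exv"][:, 0], p["exv"][:, 1]
            sigma = 0.5 * (self.exv_radius[i] + self.exv_radius[j])
            eps = np.sqrt(self.exv_eps[i] * self.exv_eps[j])
            kind = np.zeros(len(i), dtype=np.int64)
            kind[self.is_dna_site[i] & self.is_dna_site[j]] = 1
            kind[self.hps_active[i] & self.hps_active[j]] = 2
            kind[sigma <= 0] = 2
            lists.params["exv"] = (np.ascontiguousarray(sigma * sigma),
                                   np.ascontiguousarray(eps),
                                   np.ascontiguousarray(kind))
        if "ele" in p and len(p["ele"]):
            i, j = p["ele"][:, 0], p["ele"][:, 1]
            lists.params["ele"] = (np.ascontiguousarray(
                self.charges[i] * self.charges[j]),)
        if "hps" in p and len(p["hps"]):
            i, j = p["hps"][:, 0], p["hps"][:, 1]
            sig = 0.5 * (self._hps_sig[i] + self._hps_sig[j])
            lists.params["hps"] = (
                np.ascontiguousarray(sig * sig),
                np.ascontiguousarray(0.5 * (self._hps_lam[i]
                                            + self._hps_lam[j])),
                np.ascontiguousarray(np.sqrt(self._hps_eps[i]
                                             * self._hps_eps[j])))

    def _filter_intra_rna(self, pairs):
        if self.options.get("intra_rna_ele", False) or pairs.size == 0:
            return pairs
        is_rna = self.topology.particles.mol_class == "rna"
        mask = ~(is_rna[pairs[:, 0]] & is_rna[pairs[:, 1]])
        return np.ascontiguousarray(pairs[mask])

    def _expand_pwm_pairs(self, raw):
        """(base, ca) candidate pairs -> (site, base) rows + per-row eps."""
        rows = []
        eps = []
        pw = self.topology.pwmcos
        scores = self.pwm.scores
        nm = self.pwm.n_contacts
        code_of = self._bp_maps[3]
        for b, ca in raw:
            for s in self._ca_to_sites.get(int(ca), ()):
                c = code_of[b]
                if c < 0:
                    continue
                row = c if pw.strand[s] == 0 else 3 - c
                col = pw.col[s]
                e = self.pwm_gamma * (scores[row, col] / nm[col]
                                      + self.pwm_shift)
                rows.append((s, int(b)))
                eps.append(e)
        if rows:
            return (np.array(rows, dtype=np.int64), np.array(eps))
        return (np.empty((0, 2), dtype=np.int64), np.empty(0))

    # ------------------------------------------------------------------
    # energy / forces
    # ------------------------------------------------------------------
    def energy_forces(self, frame: Frame | np.ndarray, lists=None,
                      brute=False) -> EnergyReport:
        """Total potential energy and analytic forces for one frame.

        ``lists`` may be a prebuilt :class:`NeighborLists`; with ``brute``
        the all-pairs oracle path is used instead.
        """
        if isinstance(frame, Frame):
            pos = frame.positions
            box = frame.box
        else:
            pos = np.asarray(frame, dtype=float)
            box = None
        pos = np.ascontiguousarray(pos)
        pbc = box is not None
        boxa = np.ascontiguousarray(box, dtype=float) if pbc else _DUMMY_BOX
        if lists is None:
            lists = (self.brute_force_lists(pos) if brute
                     else self.build_neighbor_lists(pos, box))
        F = np.zeros_like(pos)
        terms = {}
        t = self.topology
        if len(t.bonds.idx):
            terms["bond"] = K.bonds_ef(pos, *self._bonds, boxa, pbc, F)
        if len(t.angles.idx):
            terms["angle"] = K.angles_ef(
                pos, *self._angles, self.angle_tab_ids,
                self.bank.x0, self.bank.dx, self.bank.nseg, self.bank.seg0,
                self.bank.lo, self.bank.hi, self.bank.breaks, self.bank.coefs,
                boxa, pbc, F, self.clamp_counter)
        if len(t.dihedrals.idx):
            terms["dihedral"] = K.dihedrals_ef(
                pos, *self._dihedrals, self.dihedral_tab_ids,
                self.bank.x0, self.bank.dx, self.bank.nseg, self.bank.seg0,
                self.bank.breaks, self.bank.coefs, boxa, pbc, F)
        if len(t.contacts.idx):
            terms["contact_go"] = K.go_contacts_ef(
                pos, *self._contacts, boxa, pbc, F)
        if len(t.gauss13.idx):
            terms["gauss13"] = K.gauss_pairs_ef(
                pos, *self._gauss13, boxa, pbc, F)
        if t.stacks is not None and len(t.stacks.idx):
            terms["base_stack"] = K.stack_ef(pos, *self._stacks, boxa, pbc, F)
        p = lists.pairs
        if "exv" in p and len(p["exv"]):
            terms["exv"] = K.exv_pairs_ef(
                pos, p["exv"], *lists.params["exv"], boxa, pbc, F)
        if "ele" in p and len(p["ele"]):
            terms["ele"] = K.ele_pairs_ef(
                pos, p["ele"], *lists.params["ele"],
                COULOMB / self.env.eps_r, self.env.debye_length,
                self.cutoff["ele"], boxa, pbc, F)
        if "hps" in p and len(p["hps"]):
            terms["hps"] = K.hps_pairs_ef(
                pos, p["hps"], *lists.params["hps"],
                self.cutoff["hps"], boxa, pbc, F)
        if "bp" in p and len(p["bp"]):
            sugar_of, base5_of, base3_of, code_of = self._bp_maps
            terms["base_pair"] = K.basepair_ef(
                pos, p["bp"], sugar_of, code_of, *self._wc,
                self.cutoff["bp"], boxa, pbc, F)
            terms["cross_stack"] = K.cross_stack_ef(
                pos, p["bp"], sugar_of, base3_of, code_of, *self._cs,
                self.cutoff["bp"], boxa, pbc, F)
        if "pwmcos" in p:
            site_base, eps = p["pwmcos"]
            if len(site_base):
                sugar_of, base5_of, base3_of, _ = self._bp_maps
                (ca, cprev, cnext, col, strand, r0, th1, th2, th3, w,
                 gam) = self._pwm_sites
                terms["pwmcos"] = K.pwmcos_ef(
                    pos, site_base, ca, cprev, cnext, eps, r0, th1, th2, th3,
                    w, gam, sugar_of, base5_of, base3_of, boxa, pbc, F)
        if t.hbsites is not None and len(t.hbsites.p_idx):
            terms["hb"] = K.hb_sites_ef(pos, *self._hb, boxa, pbc, F)
        return EnergyReport(terms=terms, forces=F)

    # convenience
    def energy(self, frame, **kw) -> float:
        return self.energy_forces(frame, **kw).total


# ---------------------------------------------------------------------------
# model-specific convenience entry points
# ---------------------------------------------------------------------------

def _require(cond, msg):
    if not cond:
        raise ValueError(msg)


def energy_aicg2p(topology, frame, system=None, **kw) -> EnergyReport:
    """Evaluate the AICG2+ energy function for one frame."""
    _require(len(topology.bonds.idx) > 0, "AICG2+ topology has no bonds")
    system = system or CGSystem(topology, **kw)
    return system.energy_forces(frame)


def energy_hps_kh(topology, frame, system=None, **kw) -> EnergyReport:
    """Evaluate the HPS/KH energy function for one frame."""
    _require(np.any(topology.particles.eps > 0),
             "HPS topology has no Ashbaugh-Hatch parameters")
    system = system or CGSystem(topology, **kw)
    return system.energy_forces(frame)


def energy_3spn2c(topology, frame, system=None, **kw) -> EnergyReport:
    """Evaluate the 3SPN.2C energy function for one frame."""
    _require(topology.stacks is not None, "3SPN.2C topology has no stacking")
    system = system or CGSystem(topology, **kw)
    return system.energy_forces(frame)


def energy_rna(topology, frame, system=None, **kw) -> EnergyReport:
    """Evaluate the structure-based RNA energy function for one frame."""
    system = system or CGSystem(topology, **kw)
    return system.energy_forces(frame)


def energy_pwmcos(topology, frame, pwm, system=None, **kw) -> EnergyReport:
    """Evaluate a topology carrying PWMcos sites (plus its other terms)."""
    _require(topology.pwmcos is not None, "topology has no PWMcos sites")
    system = system or CGSystem(topology, pwm=pwm, **kw)
    return system.energy_forces(frame)


def energy_hb(topology, frame, system=None, **kw) -> EnergyReport:
    """Evaluate a topology carrying backbone-HB sites."""
    _require(topology.hbsites is not None, "topology has no HB sites")
    system = system or CGSystem(topology, **kw)
    return system.energy_forces(frame)


def total_energy_forces(system: CGSystem, frame, lists=None) -> EnergyReport:
    """Per-term decomposition and exact gradient of the total energy."""
    return system.energy_forces(frame, lists=lists)


def pwm_to_epsilon(pwm, m: int, base: str, gamma: float,
                   eps_shift: float) -> float:
    """PWM element -> Gaussian well depth: eps = gamma * (e_m(b)/N_m + eps')."""
    from .topology import BASE_CODES
    row = BASE_CODES[base]
    if pwm.n_contacts[m] < 1:
        raise ValueError("N_m must be >= 1")
    return gamma * (pwm.scores[row, m] / pwm.n_contacts[m] + eps_shift)
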