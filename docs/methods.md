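# Methods

This note documents the models implemented in `rescg`, the conventions and
numerical choices behind them, what the synthetic generators emulate, and
the limits of what the tests demonstrate.

## Unit system and constants

Å, fs, amu, kcal/mol, elementary charge, radian.  Because these are not
mutually consistent, accelerations carry the factor 4.184×10⁻⁴
(Å/fs² per (kcal/mol/Å)/amu); the dynamics code folds it into the masses
once (`m_int = m / 4.184e-4`) so kinetic energies come out in kcal/mol
directly.  k_B = 1.987204×10⁻³ kcal/mol/K; Coulomb constant
332.0637 kcal·Å/(mol·e²).  All constants live in `rescg.constants`.

## Basic interaction terms

Bond: harmonic k(b−b₀)² or quartic k₂(b−b₀)² + k₄(b−b₀)⁴.
Angle: harmonic k(θ−θ₀)² or a tabulated statistical term evaluated through
a C¹ cubic spline.  Dihedral: periodic Σₙ kₙ[1+cos n(φ−φ₀)], Gaussian
−ε exp(−Δφ²/2σ²) with Δφ wrapped into (−π, π], or a periodic tabulated
spline.  Pair terms: the 12-10 Gō contact ε[5(σ/r)¹²−6(σ/r)¹⁰] (minimum
−ε at the native distance σ), 12-6 Lennard-Jones, two excluded-volume
forms (LJ truncated and shifted at its minimum with cutoff σ, and
ε(σ/r)¹² − 2⁻¹²ε with cutoff 2σ), a distance Gaussian, and the Morse well
split into an ungated repulsive part (zero beyond r₀) and an attractive
part (constant −ε inside r₀).  The angle-gating modulator is
f(Δθ) = 1 for |Δθ|<γ, 1−cos²(πΔθ/2γ) on γ≤|Δθ|≤2γ, 0 beyond; it is C¹ at
both joins, which keeps all gated forces continuous.

Electrostatics is Debye–Hückel,
E = 332.0637·q₁q₂·exp(−r/λ_D)/(ε_r·r), with the solution permittivity
ε_r = e(T)·a(C), e(T) = 249.4 − 0.788 T + 7.20×10⁻⁴ T²,
a(C) = 1 − 0.2551 C + 5.151×10⁻² C² − 6.889×10⁻³ C³, and
λ_D = 0.019885·√(ε_r T / I) Å with I in mol/L.  Ionic strength defaults to
the salt molarity (1:1 salt).  At 300 K and 150 mM, ε_r = 74.91,
λ_D = 7.70 Å, and |E(52 Å)| = 9.9×10⁻⁵ kcal/mol for unit charges — which
is why 52 Å is the default electrostatic cutoff.  The analogous
Lennard-Jones criterion |E(r_C)| = 10⁻⁴ε has its largest root at
r_C ≈ 5.848 σ (the quadratic in (σ/r)⁶ is solvable in closed form; the
bisection in `lj_cutoff_ratio` reproduces it to 10⁻⁹).

## Models

**AICG2+** (folded proteins): harmonic bonds (k = 110.4 kcal/mol/Å²,
native b₀), tabulated flexible angles on every triplet, 1–3 Gaussians
(ε = 1.0, w = 0.15 Å, native r₀) and Gaussian dihedrals (ε = 0.5,
σ = 0.15 rad, native φ₀) outside flexible regions, tabulated flexible
dihedrals on every quadruplet, Gō contacts between residues whose heavy
atoms approach within 6.5 Å in the native structure (once per residue
pair, intra-chain separation ≥ 4; σ is the native Cα–Cα distance; uniform
fallback ε = 0.5 kcal/mol), and r⁻¹² excluded volume for everything else
with σ = (ς₁+ς₂)/2 and a uniform ς = 2.0 Å default.  Designated flexible
regions (e.g. terminal tails) keep only bond + tabulated local terms.
The statistical angle/dihedral tables are parameter *data*: the packaged
`aicg_flex_*.csv` files are smooth generic stand-ins with the documented
two-column schema, and real Boltzmann-inversion tables drop in unchanged.

**HPS / KH** (disordered regions, one-bead RNA): harmonic bonds
(k = 2.39 kcal/mol/Å², b₀ = 3.8 Å for protein, 5.0 Å for one-bead RNA),
Debye–Hückel between charged residues, and the Ashbaugh–Hatch pair term
E = E_LJ + (1−λ)ε for r ≤ 2^{1/6}σ, λ·E_LJ beyond, with arithmetic-mean
σ and λ and geometric-mean ε (ε = 0.2 kcal/mol uniform).  The packaged
per-residue σ/λ table is the standard hydropathy scale normalized to
[0, 1].  The KH variant shares the machinery; its packaged table is a
synthetic schema example (see the file header) and published tables are
accepted through the same columns.

**3SPN.2C-style DNA**: quartic bonds (k₂ = 0.6, k₄ = 600), harmonic
angles (k = 50 kcal/mol/rad²), Gaussian + periodic backbone dihedrals,
and three angle-gated Morse site terms with reference geometry taken from
the built reference structure:

- base stacking, per intra-strand step (S_i, B_i, B_{i+1}):
  E = rep(r) + f(Δθ_BS)·attr(r), r between the bases, θ_BS the
  S_i–B_i–B_{i+1} angle;
- Watson–Crick pairing, over base–base candidates within the 18 Å cutoff
  (A·T and G·C only): E = rep(r) + ½(1+cos Δφ)·f(Δθ₁)f(Δθ₂)·attr(r) with
  θ₁ = S_i–B_i–B_j, θ₂ = B_i–B_j–S_j, φ the S–B–B–S dihedral; the
  repulsive Morse part is left ungated;
- cross stacking, for each WC-compatible candidate: the 3′ sequence
  neighbors across the duplex interact through f(Δθ₃)f(Δθ_CS)·attr(r).

This geometry map (which sites define each angle) is the package's
convention, encoded in one place per term and swappable through the site
records.  Pair-type reference values (r₀, θ₀, φ₀) are computed from the
package's own ideal base-pair template and uniform-helix step so builder
and energy function are mutually consistent by construction.  Phosphates
carry −1 e (scalable); intra-strand stacking partners and native WC
partners are excluded from the excluded-volume term but of course remain
base-pair candidates.

**Structure-based RNA** (three beads per nucleotide): harmonic
bonds/angles and periodic backbone dihedrals at native values, Gō
contacts (ε = 0.8 default), excluded volume, optional intra-RNA
phosphate electrostatics (off by default; inter-molecular electrostatics
always available when partner charges exist).

**PWMcos / backbone HB** (protein–DNA): each site record anchors a
DNA-binding Cα (with its two chain neighbors) to a PWM column; for a base
b near the site, E = −ε·exp(−(r−r₀)²/2w²)·f(Δθ₁)f(Δθ₂)f(Δθ₃) with
ε = γ(e_PWM,m(b)/N_m + ε′), θ₁ the sugar–base–Cα angle, θ₂ the angle of
the strand direction (5′→3′ neighbor bases) against base→Cα, θ₃ the angle
of the Cα backbone direction (j−1 → j+1) against base→Cα.  Sites come in
complementary pairs (one per strand; the complementary site reads the
complement row of the PWM), which realizes the two-term sum per column
without double counting.  The HB variant anchors the phosphate instead of
the base and uses two modulators.  Both terms cut off at r₀ + 5 Å.
Defaults: w = 1.0 Å, γ (modulator half-width) = 10°.

**Cross-molecule terms** follow a validated combination matrix: excluded
volume always (σ from the radius combination rule), electrostatics
optional, Gō contacts between molecules when detected, PWMcos/HB only for
protein + DNA.  Disallowed combinations (e.g. the Ashbaugh–Hatch term on
three-bead DNA sites) raise at construction.

## Neighbor lists

Every nonbonded term keeps its own candidate pair list built by a cell
linked list: per term, a particle subset (all excluded-volume particles;
charged particles for electrostatics — for DNA that is only the ~1/3 of
sites that are phosphates; bases for pairing; bases × site-Cαs for
PWMcos) and a neighboring-cell set {C_k : r_min(C_i, C_k) < r_P}.  Pair
lists are rebuilt every 20 steps (configurable); pair-list distances are
the cutoffs plus ~5 Å (ele 52/57, Ashbaugh–Hatch 39/44, base pairing
18/23, PWMcos/HB −/23, excluded volume −/15 Å).  Periodic boxes must
measure ≥ 3× the largest pair-list distance per axis, which guarantees
single-image minimum-image arithmetic.

Numerical choices: cells are ~half the shortest pair-list distance — the
per-term stencils then hug the r_min criterion sphere much more tightly
than r_P-sized cells, which profiling showed cuts the candidate scan
several-fold; stencils and resolved neighboring-cell tables are cached
per box; pairs are stored once (i < j), grouped by i, with per-pair
combination-rule parameters precomputed at rebuild time.  Correctness is
pinned by exact set-equality tests against the all-pairs oracle and by
1e-10-relative energy agreement between the list-based and direct-sum
paths.

## Dynamics

Velocity Verlet with a Langevin thermostat, implemented as half-kick /
drift / half-kick; the Langevin force is −∇V − mγv + mξ with the friction
applied to the half-step velocity, and each noise component has variance
2γk_BT/(mΔt).  With γ = 0 the scheme reduces to plain energy-conserving
Verlet (drift < 10⁻⁴ kcal/mol per particle over 10⁴ steps at Δt = 10 fs
on the bonded test fixture; harmonic period reproduced to < 0.1%).
Δt defaults to 10 fs, set by the stiffest bead vibrations.  Time-scale
caveat: as with all implicit-solvent CG dynamics, the mapping from
simulation steps to physical time is system-dependent; treat reported
times as internal units.

The friction default is γ = 1/ps, deliberately configurable and flagged
here as a free parameter (it sets sampling efficiency, not the sampled
ensemble).  Condensation protocols use γ = 0.01/ps, the low-friction
convention of slab studies of disordered-protein phase behavior.

Noise is generated by a counter-based Philox stream keyed by
(seed, step): trajectories are bit-identical for a seed regardless of
scheduling, and runs restart bit-identically when the serialized state
(including the live pair lists, whose build phase fixes the
floating-point summation order) is carried over.  The first step's
"previous force" is the force of the initial configuration (evaluated,
not zeroed).  Initial velocities default to a seeded Maxwell–Boltzmann
draw.  Angle/dihedral forces near collinear geometries are kept finite by
clamping the relevant sine/cross-product magnitudes (10⁻⁶ / 10⁻¹²); the
energies are exact away from the degenerate set.

## Synthetic generators and what the tests show

The generators create the study systems deterministically from a seed:
ideal α-helices with pseudo backbone atoms (contact-detection oracle
fixtures), fully self-avoiding random-walk IDP chains (bond 3.8 Å,
non-bonded separation ≥ 4.2 Å), sequence-built dsDNA (base-pair frames
composed from a packaged dinucleotide step table through the mid-step
triad algorithm; pure twist/rise composes an exact helix, which the tests
exploit as a closed-form oracle), and slab packings of replicated chains
with rejection sampling against close contacts.

The slab condensation check uses 20 chains of the 163-residue FUS
low-complexity sequence in an 18×18×34 nm periodic box — the chain
density of the full 120-chain, 18×18×200 nm slab setup, with the box
shortened in z only because x and y are already at the 3×r_P lower bound.
Preparation mirrors the usual protocol: one chain is collapsed in a
30 000-step single-chain run, replicated into the box, and the packing
relaxed for 2 000 small steps.  Production runs at 300 K with γ = 0.01/ps
until the largest connected chain cluster (chains linked when any
inter-chain bead pair is within 8 Å) exceeds 85% of all chains, with a
60 000-step-per-seed budget as the package's compute scale; success
within the budget implies success within any larger one.  Across seeds
1–3 the largest-cluster fraction reaches 0.85–0.95 within 5 000–15 000
steps.  What this does and does not show: the scaled system demonstrates
that the Ashbaugh–Hatch model, neighbor engine and thermostat drive
spontaneous multi-chain condensation at slab density; it does not measure
coexistence densities or interfacial properties, which need the full
system size and ~10⁷-step trajectories.

Synthetic fixtures also stand in for experimental structures everywhere
in the tests (no downloads); mapping real PDB/mmCIF entries uses the same
code path through gemmi.

## Parameter data

All numeric model parameters ship as plain-text files under `rescg/data/`
with documented schemas (per-residue hydropathy tables, DNA model
constants, base-step geometry, flexible-term tables) so published or
recalibrated sets can be substituted without touching code.  Shipped
values are package defaults chosen in the conventional range for each
model family; the KH table in particular is a synthetic schema example
and is labelled as such in the file.

## Known limitations

Orthorhombic boxes and minimum image only (no Ewald/PME; Debye–Hückel is
short-ranged by construction).  No barostat, no enhanced sampling, no
multi-basin Gō mixing, no virial/pressure.  One energy/force path per
term (compiled kernels) with a brute-force pair-enumeration oracle for
testing; no MPI/thread parallelism — the target scale is the desk-sized
end of residue-level CG work.  The Gō contact rule counts one contact per
residue pair and excludes intra-chain pairs closer than four residues in
sequence; 3′-terminal phosphates are assumed absent (strands map to
3n − 1 beads).
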