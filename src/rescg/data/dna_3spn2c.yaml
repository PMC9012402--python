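# 3SPN.2C-style DNA model constants (package defaults; reference values
# r0/theta0/phi0 for the bonded and site terms come from the built
# reference structure, not from this file).
bond:
  k2: 0.60        # kcal/mol/A^2
  k4: 600.0       # kcal/mol/A^4
angle:
  k: 50.0         # kcal/mol/rad^2
dihedral:
  gaussian_eps: 1.67    # kcal/mol
  gaussian_sigma: 0.30  # rad
  periodic_k: 0.478     # kcal/mol
stack:
  eps: 3.60       # kcal/mol, uniform default over the 16 steps
  alpha: 3.0      # 1/A
  gamma: 0.2618   # rad (pi/12 modulator half-width)
basepair:
  AT:
    eps: 4.00     # kcal/mol
    alpha: 2.0    # 1/A
    gamma: 0.1309 # rad (pi/24)
  GC:
    eps: 5.06
    alpha: 2.0
    gamma: 0.1309
cross_stack:
  eps: 0.40       # kcal/mol
  alpha: 4.0      # 1/A
  gamma: 0.1309   # rad
site_masses:      # amu, heavy-atom group masses
  P: 94.97
  S: 83.11
  A: 134.12
  C: 110.09
  G: 150.12
  T: 125.11
exv_radius:       # per-site excluded-volume radius (A)
  P: 2.25
  S: 3.10
  B: 2.70
phosphate_charge: -1.0
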