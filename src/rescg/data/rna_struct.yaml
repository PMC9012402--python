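# Structure-based three-bead RNA model constants (package defaults; the
# fluctuation-matched published values are external parameter data and can
# replace these through the same keys).
bond_k: 15.0          # kcal/mol/A^2
angle_k: 10.0         # kcal/mol/rad^2
dihedral_k: 1.0       # kcal/mol
contact_eps: 0.80     # kcal/mol
contact_cutoff: 6.5   # A
exv_radius:
  P: 2.25
  S: 2.90
  B: 2.80
site_masses:
  P: 94.97
  S: 99.11
  A: 134.12
  C: 110.09
  G: 150.12
  U: 111.07
phosphate_charge: -1.0
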