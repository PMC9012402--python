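# AICG2+ protein model constants (package defaults).  The statistical
# flexible-angle/dihedral tables and the sequence-dependent contact
# energies are external parameter data; the generic tables shipped with
# the package (aicg_flex_*.csv) are smooth stand-ins with the documented
# schema, and a uniform contact epsilon is used when no table is given.
bond_k: 110.40          # kcal/mol/A^2
contact_eps: 0.50       # kcal/mol, uniform fallback
gauss13_eps: 1.00       # kcal/mol
gauss13_w: 0.15         # A
dihedral_gauss_eps: 0.50  # kcal/mol
dihedral_gauss_sigma: 0.15  # rad
exv_radius: 2.00        # A (sigma = (r1+r2)/2 combination)
contact_cutoff: 6.5     # A, heavy-atom native-contact criterion
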