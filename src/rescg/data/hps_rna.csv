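# One-bead-per-nucleotide RNA parameters for the Ashbaugh-Hatch pair model
# (package defaults; the schema accepts user replacements).  Mass is the
# nucleotide-monophosphate residue mass, charge the backbone phosphate.
residue,mass,charge,sigma,lambda,eps
A,329.21,-1.0,9.00,0.90,0.2
C,305.18,-1.0,9.00,0.90,0.2
G,345.21,-1.0,9.00,0.90,0.2
U,306.17,-1.0,9.00,0.90,0.2
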