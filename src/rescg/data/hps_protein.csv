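# HPS amino-acid parameters: residue-level mass (amu), net charge (e),
# Lennard-Jones diameter sigma (A), hydropathy lambda (Kapcha-Rossky scale
# normalized to [0, 1]), pair well depth eps (kcal/mol, uniform).
residue,mass,charge,sigma,lambda,eps
ALA,71.08,0.0,5.04,0.730,0.2
ARG,156.19,1.0,6.56,0.000,0.2
ASN,114.10,0.0,5.68,0.432,0.2
ASP,115.09,-1.0,5.58,0.378,0.2
CYS,103.14,0.0,5.48,0.595,0.2
GLN,128.13,0.0,6.02,0.514,0.2
GLU,129.12,-1.0,5.92,0.459,0.2
GLY,57.05,0.0,4.50,0.649,0.2
HIS,137.14,0.0,6.08,0.514,0.2
ILE,113.16,0.0,6.18,0.973,0.2
LEU,113.16,0.0,6.18,0.973,0.2
LYS,128.17,1.0,6.36,0.514,0.2
MET,131.19,0.0,6.18,0.838,0.2
PHE,147.18,0.0,6.36,1.000,0.2
PRO,97.12,0.0,5.56,1.000,0.2
SER,87.08,0.0,5.18,0.595,0.2
THR,101.10,0.0,5.62,0.676,0.2
TRP,186.21,0.0,6.78,0.946,0.2
TYR,163.18,0.0,6.46,0.865,0.2
VAL,99.13,0.0,5.86,0.892,0.2
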