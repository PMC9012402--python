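# SYNTHETIC schema example for the Kim-Hummer variant of the Ashbaugh-Hatch
# pair model.  Real KH parameters derive from the Miyazawa-Jernigan contact
# matrix; this file is a placeholder that documents the per-residue schema
# (same columns as hps_protein.csv) so users can drop in a published table.
# Values below mirror the HPS hydropathies with a +/- sign convention and
# are NOT the published KH parameters.
residue,mass,charge,sigma,lambda,eps
ALA,71.08,0.0,5.04,0.460,0.2
ARG,156.19,1.0,6.56,-0.460,0.2
ASN,114.10,0.0,5.68,-0.136,0.2
ASP,115.09,-1.0,5.58,-0.244,0.2
CYS,103.14,0.0,5.48,0.190,0.2
GLN,128.13,0.0,6.02,0.028,0.2
GLU,129.12,-1.0,5.92,-0.082,0.2
GLY,57.05,0.0,4.50,0.298,0.2
HIS,137.14,0.0,6.08,0.028,0.2
ILE,113.16,0.0,6.18,0.946,0.2
LEU,113.16,0.0,6.18,0.946,0.2
LYS,128.17,1.0,6.36,0.028,0.2
MET,131.19,0.0,6.18,0.676,0.2
PHE,147.18,0.0,6.36,1.000,0.2
PRO,97.12,0.0,5.56,1.000,0.2
SER,87.08,0.0,5.18,0.190,0.2
THR,101.10,0.0,5.62,0.352,0.2
TRP,186.21,0.0,6.78,0.892,0.2
TYR,163.18,0.0,6.46,0.730,0.2
VAL,99.13,0.0,5.86,0.784,0.2
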