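# Sequence-dependent base-step helical parameters for the ten unique
# dinucleotides (package defaults in the crystallographic-consensus range;
# the schema accepts user replacements).  Angles in degrees, displacements
# in A.  Steps for the six missing dinucleotides follow by complementarity.
step,twist,tilt,roll,shift,slide,rise
AA,35.3,-1.4,0.7,-0.03,-0.08,3.27
AT,31.2,0.0,1.1,0.00,-0.59,3.31
AC,31.5,-0.1,0.7,0.13,-0.58,3.36
AG,31.9,-1.7,4.5,0.09,-0.25,3.34
GA,36.3,-1.5,1.9,-0.28,0.09,3.37
GG,32.9,-0.1,3.6,0.05,-0.22,3.42
GC,33.6,0.0,0.3,0.00,-0.38,3.40
TA,36.3,0.0,3.3,0.00,0.05,3.42
TG,35.8,0.5,5.7,0.09,0.53,3.33
CG,36.1,0.0,5.4,0.00,0.41,3.39
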