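# Generic flexible-angle table (theta rad, energy kcal/mol).
# Schema: uniform grid, natural-spline interpolated; replaceable
# by residue-type statistical tables with the same two columns.
theta,energy
0.6000,4.68767825
0.6500,4.32077218
0.7000,3.97036679
0.7500,3.63912119
0.8000,3.33237061
0.8500,3.05811665
0.9000,2.82388418
0.9500,2.62974072
1.0000,2.46127747
1.0500,2.29029651
1.1000,2.08750000
1.1500,1.84029651
1.2000,1.56127747
1.2500,1.27974072
1.3000,1.02388418
1.3500,0.80811665
1.4000,0.63237061
1.4500,0.48912119
1.5000,0.37036679
1.5500,0.27077218
1.6000,0.18767825
1.6500,0.12003526
1.7000,0.06750598
1.7500,0.03000087
1.8000,0.00750011
1.8500,0.00000001
1.9000,0.00750000
1.9500,0.03000000
2.0000,0.06750000
2.0500,0.12000000
2.1000,0.18750000
2.1500,0.27000000
2.2000,0.36750000
2.2500,0.48000000
2.3000,0.60750000
2.3500,0.75000000
2.4000,0.90750000
2.4500,1.08000000
2.5000,1.26750000
2.5500,1.47000000
2.6000,1.68750000
2.6500,1.92000000
2.7000,2.16750000
2.7500,2.43000000
2.8000,2.70750000
2.8500,3.00000000
2.9000,3.30750000
2.9500,3.63000000
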