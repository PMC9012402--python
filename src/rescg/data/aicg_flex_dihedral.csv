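# Generic flexible-dihedral table (phi rad, energy kcal/mol),
# periodic over (-pi, pi]; same replaceable schema as the angle table.
phi,energy
-3.14159265,1.11011380
-3.05432619,1.04167318
-2.96705973,0.96694809
-2.87979327,0.88681548
-2.79252680,0.80238849
-2.70526034,0.71499277
-2.61799388,0.62613555
-2.53072742,0.53746864
-2.44346095,0.45074620
-2.35619449,0.36777857
-2.26892803,0.29038360
-2.18166156,0.22033668
-2.09439510,0.15932128
-2.00712864,0.10888109
-1.91986218,0.07037555
-1.83259571,0.04493981
-1.74532925,0.03345055
-1.65806279,0.03649851
-1.57079633,0.05436873
-1.48352986,0.08702900
-1.39626340,0.13412697
-1.30899694,0.19499595
-1.22173048,0.26866939
-1.13446401,0.35390350
-1.04719755,0.44920748
-0.95993109,0.55288047
-0.87266463,0.66305412
-0.78539816,0.77773957
-0.69813170,0.89487763
-0.61086524,1.01239039
-0.52359878,1.12823318
-0.43633231,1.24044502
-0.34906585,1.34719635
-0.26179939,1.44683262
-0.17453293,1.53791246
-0.08726646,1.61923938
0.00000000,1.68988620
0.08726646,1.74921147
0.17453293,1.79686748
0.26179939,1.83279976
0.34906585,1.85723817
0.43633231,1.87067980
0.52359878,1.87386445
0.61086524,1.86774345
0.69813170,1.85344271
0.78539816,1.83222143
0.87266463,1.80542750
0.95993109,1.77445123
1.04719755,1.74067872
1.13446401,1.70544635
1.22173048,1.66999779
1.30899694,1.63544495
1.39626340,1.60273388
1.48352986,1.57261684
1.57079633,1.54563127
1.65806279,1.52208634
1.74532925,1.50205746
1.83259571,1.48538881
1.91986218,1.47170395
2.00712864,1.46042394
2.09439510,1.45079252
2.18166156,1.44190744
2.26892803,1.43275698
2.35619449,1.42226043
2.44346095,1.40931128
2.53072742,1.39282169
2.61799388,1.37176682
2.70526034,1.34522755
2.79252680,1.31243032
2.87979327,1.27278262
2.96705973,1.22590312
3.05432619,1.17164527
3.14159265,1.11011380
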