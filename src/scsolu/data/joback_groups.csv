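# Joback group contributions: dTc, dPc (for Tc/Pc sums), dTb (boiling point
# increments, K), atoms = heavy + hydrogen atom count of the group.
group,dTc,dPc,dTb,atoms
-CH3,0.0141,-0.0012,23.58,4
>CH2,0.0189,0.0000,22.88,3
>CH-,0.0164,0.0020,21.74,2
>C<,0.0067,0.0043,18.25,1
=CH2,0.0113,-0.0028,18.18,3
=CH-,0.0129,-0.0006,24.96,2
=C<,0.0117,0.0011,24.14,1
-CH2- (ring),0.0100,0.0025,27.15,3
>CH- (ring),0.0122,0.0004,21.78,2
>C< (ring),0.0042,0.0061,21.32,1
=CH- (ring),0.0082,0.0011,26.73,2
=C< (ring),0.0143,0.0008,31.01,1
-F,0.0111,-0.0057,-0.03,1
-Cl,0.0105,-0.0049,38.13,1
-Br,0.0133,0.0057,66.86,1
-OH (alcohol),0.0741,0.0112,92.88,2
-OH (phenol),0.0240,0.0184,76.34,2
-O- (nonring),0.0168,0.0015,22.42,1
>C=O (nonring),0.0380,0.0031,76.75,2
-CHO,0.0379,0.0030,72.24,3
-COOH,0.0791,0.0077,169.09,4
-COO-,0.0481,0.0005,81.10,3
-NH2,0.0243,0.0109,73.23,3
>NH,0.0295,0.0077,50.17,2
>NH (ring),0.0130,0.0114,52.82,2
>N- (nonring),0.0169,0.0074,11.74,1
-NO2,0.0437,0.0064,152.54,3
-SH,0.0031,0.0084,63.56,2
-S- (nonring),0.0119,0.0049,68.78,1
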