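# First-order group contributions w1 for the Constantinou-Gani acentric
# factor, omega = 0.4085 [ln(sum N_k w1_k + 1.1507)]^(1/0.5050).
# source "lit" = transcribed literature value; "cal" = calibrated in-repo
# against the experimental acentric factor of the reference compound named,
# because the full published table is not redistributable here.
group,w1,source
CH3,0.296,lit
CH2,0.147,lit
CH,-0.071,lit
C,-0.351,lit
ACH,0.14878,cal:benzene
AC,-0.02144,cal:biphenyl
ACCH3,0.33231,cal:toluene
ACCl,0.28426,cal:chlorobenzene
ACF,0.27048,cal:fluorobenzene
COOH,1.46677,cal:acetic acid
NH,0.32974,cal:diethylamine
OH,1.45605,cal:1-butanol
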