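residue,identity,nucleus,P1,P2,P3,P4,P5,P6,ambiguity
A,β-D-Glcp,H,4.35,3.36,3.68,3.70,3.51,3.70,"H6a/H6b 3.70/3.84"
A,β-D-Glcp,C,103.83,74.36,75.46,76.90,75.76,61.62,"P2:a;P3:b;P5:b"
B,α-L-6dTalp,H,5.25,3.80,3.88,3.86,4.06,1.22,
B,α-L-6dTalp,C,102.10,70.49,65.93,81.50,67.74,16.38,"P2:c"
C,α-D-GalpA,H,4.96,3.87,4.00,4.38,4.62,,
C,α-D-GalpA,C,100.69,69.66,71.34,77.33,72.84,175.26,
D,α-D-Galp,H,4.94,3.80,3.88,4.06,4.30,3.73,
D,α-D-Galp,C,101.16,69.31,70.43,78.63,72.22,60.89,"P3:c;P5:d"
E,α-D-Galp,H,5.66,3.97,3.98,4.08,3.96,3.78,
E,α-D-Galp,C,97.47,74.22,68.16,79.19,72.02,60.89,"P2:a;P5:d"
F,α-D-Glcp,H,5.13,3.54,3.71,3.38,3.90,3.71,
F,α-D-Glcp,C,97.47,72.54,73.74,70.80,72.80,61.62,
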