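item_id,a,b1,b2,b3,b4
488R1r,3.45,0.05,0.64,1.40,1.96
461R1r,3.60,-0.03,0.45,1.11,1.68
5041R1r,4.17,0.05,0.52,1.06,1.64
5035R1r,3.95,-0.10,0.44,1.05,1.59
711R1r,3.51,-0.26,0.28,0.96,1.56
228R1r,4.30,-0.50,0.11,0.93,1.55
712R1r,4.36,0.07,0.63,1.31,1.78
3952aR2r,3.26,-0.25,0.46,1.15,1.91
2227R1r,2.63,-0.03,0.60,1.32,1.91
2697R1r,1.78,-0.90,-0.12,0.92,1.82
5047R1r,1.74,-1.24,-0.51,0.49,1.38
679aR2r,3.22,0.41,1.00,1.58,2.04
7010,3.51,0.03,0.50,1.08,1.69
9001r,2.88,0.58,1.02,1.56,2.03
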