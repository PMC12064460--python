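item_id,a,b1,b2,b3,b4
2220R2r,2.67,0.40,0.94,1.64,2.21
713R1r,3.43,-0.47,0.15,0.84,1.55
227bR1r,3.57,0.17,0.79,1.51,2.06
5044R1r,2.80,-0.45,0.20,1.13,1.86
3459bR1r,2.43,0.45,1.11,1.71,2.38
2230R1r,1.49,0.36,1.15,1.83,2.43
231R1r,2.70,0.36,0.97,1.66,2.24
3150bR2r,2.73,0.04,0.53,1.21,1.76
7005,2.05,0.17,0.80,1.44,1.97
3021R1r,1.88,0.95,1.66,2.39,3.18
3149R1r,2.18,0.86,1.36,2.05,2.69
3459aR1r,2.74,0.50,1.05,1.65,2.24
3977R1r,2.38,0.72,1.21,1.68,2.06
7006,1.90,0.30,1.00,1.66,2.37
953R1r,2.18,-0.43,0.24,0.98,1.78
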