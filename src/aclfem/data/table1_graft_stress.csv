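flexion_angle,Circular,Rounded rectangular 1,Rounded rectangular 2,Rounded rectangular 3,Rounded rectangular 4
0,3.37,3.36,3.01,2.97,2.89
30,4.45,4.44,4.02,4.00,3.69
60,3.45,3.37,3.20,3.28,2.74
90,4.45,4.10,3.50,3.55,2.87
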