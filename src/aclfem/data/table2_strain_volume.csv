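flexion_angle,Circular,Rounded rectangular 1,Rounded rectangular 2,Rounded rectangular 3,Rounded rectangular 4
0,187.47,288.66,348.24,365.92,340.63
30,261.42,350.11,399.38,479.27,478.24
60,52.68,51.73,51.95,68.94,86.84
90,214.67,195.09,190.71,216.84,277.14
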