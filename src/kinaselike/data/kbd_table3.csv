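Wt,RB,HBA,HBD,SlogP,TPSA,Rings,nN,nO
1.00,0.70,0.44,0.14,0.20,0.50,0.54,0.40,0.40
0.70,1.00,0.39,0.13,0.01,0.52,0.00,0.29,0.43
0.44,0.39,1.00,0.45,-0.12,0.62,0.22,0.37,0.50
0.14,0.13,0.45,1.00,-0.11,0.51,0.08,0.21,0.23
0.20,0.01,-0.12,-0.11,1.00,-0.44,0.29,-0.13,-0.26
0.50,0.52,0.62,0.51,-0.44,1.00,0.05,0.38,0.66
0.54,0.00,0.22,0.08,0.29,0.05,1.00,0.37,-0.04
0.40,0.29,0.37,0.21,-0.13,0.38,0.37,1.00,-0.29
0.40,0.43,0.50,0.23,-0.26,0.66,-0.04,-0.29,1.00
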