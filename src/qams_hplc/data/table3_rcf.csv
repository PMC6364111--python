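injection_volume_uL,matrine,oxymatrine,catechin,rutin,ferulic_acid
3,3.80,2.99,0.38,2.29,2.37
5,3.85,3.11,0.39,2.31,2.36
10,3.81,3.03,0.39,2.30,2.41
15,3.73,2.99,0.39,2.30,2.37
20,3.82,3.01,0.38,2.33,2.40
Mean,3.80,3.03,0.39,2.31,2.38
RSD%,1.17,1.65,1.42,0.66,0.91
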