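analyte,slope,intercept,r,range_low_ug_per_ml,range_high_ug_per_ml,lod_ug_per_ml,loq_ug_per_ml
matrine,6.9958,-7.136,0.9998,23.84,715.08,0.08,0.24
gallic_acid,27.728,-3.6914,0.9999,0.89,26.64,0.07,0.21
oxymatrine,8.6405,138.3,0.9998,231.05,6931.56,0.11,0.31
catechin,37.684,4.6647,0.9999,0.11,3.42,0.01,0.04
rutin,10.578,1.9008,0.9997,0.35,10.38,0.04,0.11
ferulic_acid,10.658,18.793,0.9998,10.96,328.92,0.08,0.23
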