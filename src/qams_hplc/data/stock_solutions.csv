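analyte,stock_printed_ug_per_ml,mixed_standard_printed_ug_per_ml,stock_range_consistent_ug_per_ml
matrine,1191.8,119.18,1191.8
gallic_acid,11552.6,1155.26,44.4
oxymatrine,5.7,0.57,11552.6
catechin,44.4,4.44,5.7
rutin,848.2,84.82,17.3
ferulic_acid,17.3,1.73,548.2
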