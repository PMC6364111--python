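batch,method,matrine,gallic_acid,oxymatrine,catechin,rutin,ferulic_acid
20171201,ES,0.1190,0.0044,1.1552,3.1748e-04,1.7485e-03,0.0549
20171201,QAMS,0.1170,0.0044,1.1697,3.0986e-04,1.7752e-03,0.0564
20171201,RE,1.68,,-1.26,2.40,-1.53,-2.73
20171202,ES,0.1764,0.0061,1.3427,2.9770e-04,2.2040e-03,0.0713
20171202,QAMS,0.1787,0.0061,1.3138,3.0130e-04,2.1644e-03,0.0719
20171202,RE,-1.30,,2.15,-1.21,1.80,-0.84
20171203,ES,0.0985,0.0041,1.1542,3.5160e-04,1.5428e-03,0.0574
20171203,QAMS,0.0993,0.0041,1.1347,3.4630e-04,1.5763e-03,0.0564
20171203,RE,-0.81,,1.69,1.51,-2.17,1.74
20171204,ES,0.1242,0.0048,1.1787,3.0280e-04,1.8037e-03,0.0591
20171204,QAMS,0.1228,0.0048,1.1567,2.9970e-04,1.7855e-03,0.0567
20171204,RE,1.13,,1.87,1.02,1.01,4.06
20171205,ES,0.1130,0.0051,1.1679,3.4570e-04,1.5994e-03,0.0542
20171205,QAMS,0.1106,0.0051,1.1462,3.4050e-04,1.6311e-03,0.0538
20171205,RE,2.12,,1.86,1.50,-1.98,0.74
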