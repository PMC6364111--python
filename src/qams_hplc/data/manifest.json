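{
 "stock_solutions.csv": "b4b5359fbc569c054bbcfa6b072dd0002c1b8004ca0419c1a872cbfdf6e33b75",
 "table2_calibration.csv": "c072f1b23f857f3a2702178761c3ea9ee9fa2d7df2c2b62f9ce317794aa555b0",
 "table3_rcf.csv": "8d93ac12337c631c92094672ef99e32949a6ad291bd0b400acf8d50946256094",
 "table4_contents.csv": "f0ba68726ecf4f82e965e0d206566d9d8f7415b2e4f666dec54c3fc3df93ceb4"
}
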