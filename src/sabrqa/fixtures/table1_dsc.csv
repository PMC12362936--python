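# Transcribed per-center Dice similarity coefficients (with bootstrap 95% CIs)
# from the published results tables of a 10-center SABR dummy-run exercise
# (4 cases x {GTV, PTV}; center identifiers as printed). Test input, not output.
case_id,volume_kind,center_id,dsc,ci_low,ci_high
case1,GTV,A,0.610,0.514,0.707
case1,GTV,C,0.626,0.529,0.723
case1,GTV,D,0.007,0.000,0.100
case1,GTV,E,0.479,0.382,0.578
case1,GTV,F,0.317,0.217,0.418
case1,GTV,G,0.525,0.424,0.614
case1,GTV,H,0.508,0.401,0.617
case1,GTV,J,0.626,0.536,0.722
case1,GTV,K,0.411,0.311,0.504
case1,GTV,L,0.519,0.422,0.617
case1,PTV,A,0.384,0.290,0.486
case1,PTV,C,0.431,0.327,0.528
case1,PTV,D,0.049,0.000,0.149
case1,PTV,E,0.288,0.187,0.383
case1,PTV,F,0.235,0.141,0.334
case1,PTV,G,0.304,0.208,0.399
case1,PTV,H,0.366,0.269,0.469
case1,PTV,J,0.334,0.240,0.438
case1,PTV,K,0.491,0.389,0.588
case1,PTV,L,0.270,0.171,0.368
case2,GTV,A,0.604,0.503,0.708
case2,GTV,C,0.414,0.312,0.523
case2,GTV,D,0.000,0.000,0.095
case2,GTV,E,0.634,0.539,0.734
case2,GTV,F,0.136,0.042,0.230
case2,GTV,G,0.652,0.555,0.748
case2,GTV,H,0.692,0.590,0.787
case2,GTV,J,0.723,0.631,0.819
case2,GTV,K,0.677,0.579,0.770
case2,GTV,L,0.616,0.519,0.711
case2,PTV,A,0.516,0.413,0.612
case2,PTV,C,0.401,0.304,0.497
case2,PTV,D,0.001,0.000,0.103
case2,PTV,E,0.559,0.468,0.654
case2,PTV,F,0.174,0.076,0.274
case2,PTV,G,0.507,0.409,0.614
case2,PTV,H,0.545,0.444,0.639
case2,PTV,J,0.618,0.522,0.715
case2,PTV,K,0.566,0.472,0.662
case2,PTV,L,0.393,0.298,0.490
case3,GTV,A,0.000,0.000,0.092
case3,GTV,C,0.000,0.000,0.101
case3,GTV,D,0.005,0.000,0.105
case3,GTV,E,0.000,0.000,0.095
case3,GTV,F,0.000,0.000,0.097
case3,GTV,G,0.001,0.000,0.093
case3,GTV,H,0.000,0.000,0.098
case3,GTV,J,0.040,0.000,0.141
case3,GTV,K,0.000,0.000,0.099
case3,GTV,L,0.000,0.000,0.097
case3,PTV,A,0.106,0.009,0.204
case3,PTV,C,0.227,0.128,0.318
case3,PTV,D,0.045,0.000,0.144
case3,PTV,E,0.000,0.000,0.100
case3,PTV,F,0.002,0.000,0.096
case3,PTV,G,0.180,0.081,0.279
case3,PTV,H,0.000,0.000,0.095
case3,PTV,J,0.301,0.198,0.400
case3,PTV,K,0.000,0.000,0.098
case3,PTV,L,0.215,0.121,0.319
case4,GTV,A,0.307,0.205,0.404
case4,GTV,C,0.228,0.126,0.332
case4,GTV,D,0.000,0.000,0.095
case4,GTV,E,0.073,0.000,0.174
case4,GTV,F,0.090,0.000,0.189
case4,GTV,G,0.192,0.099,0.283
case4,GTV,H,0.324,0.228,0.420
case4,GTV,J,0.373,0.280,0.475
case4,GTV,K,0.237,0.131,0.332
case4,GTV,L,0.168,0.076,0.269
case4,PTV,A,0.187,0.097,0.288
case4,PTV,C,0.504,0.404,0.600
case4,PTV,D,0.031,0.000,0.125
case4,PTV,E,0.019,0.000,0.124
case4,PTV,F,0.021,0.000,0.111
case4,PTV,G,0.329,0.230,0.429
case4,PTV,H,0.247,0.142,0.346
case4,PTV,J,0.039,0.000,0.137
case4,PTV,K,0.122,0.026,0.221
case4,PTV,L,0.418,0.314,0.518
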