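age,sex,qx
40,female,0.000600
40,male,0.001000
41,female,0.000656
41,male,0.001072
42,female,0.000717
42,male,0.001151
43,female,0.000785
43,male,0.001240
44,female,0.000859
44,male,0.001338
45,female,0.000941
45,male,0.001446
46,female,0.001032
46,male,0.001567
47,female,0.001132
47,male,0.001701
48,female,0.001243
48,male,0.001850
49,female,0.001365
49,male,0.002016
50,female,0.001500
50,male,0.002200
51,female,0.001651
51,male,0.002410
52,female,0.001819
52,male,0.002652
53,female,0.002008
53,male,0.002929
54,female,0.002217
54,male,0.003244
55,female,0.002449
55,male,0.003599
56,female,0.002706
56,male,0.003997
57,female,0.002989
57,male,0.004437
58,female,0.003298
58,male,0.004919
59,female,0.003635
59,male,0.005441
60,female,0.004000
60,male,0.006000
61,female,0.004390
61,male,0.006592
62,female,0.004805
62,male,0.007222
63,female,0.005250
63,male,0.007896
64,female,0.005730
64,male,0.008624
65,female,0.006254
65,male,0.009417
66,female,0.006833
66,male,0.010289
67,female,0.007478
67,male,0.011257
68,female,0.008206
68,male,0.012345
69,female,0.009038
69,male,0.013581
70,female,0.010000
70,male,0.015000
71,female,0.011118
71,male,0.016641
72,female,0.012414
72,male,0.018533
73,female,0.013914
73,male,0.020707
74,female,0.015647
74,male,0.023200
75,female,0.017645
75,male,0.026048
76,female,0.019945
76,male,0.029290
77,female,0.022586
77,male,0.032967
78,female,0.025611
78,male,0.037119
79,female,0.029066
79,male,0.041785
80,female,0.033000
80,male,0.047000
81,female,0.037501
81,male,0.052851
82,female,0.042693
82,male,0.059465
83,female,0.048689
83,male,0.066947
84,female,0.055622
84,male,0.075416
85,female,0.063652
85,male,0.085005
86,female,0.072962
86,male,0.095870
87,female,0.083771
87,male,0.108186
88,female,0.096335
88,male,0.122154
89,female,0.110959
89,male,0.138005
90,female,0.128000
90,male,0.156000
91,female,0.146582
91,male,0.175884
92,female,0.167861
92,male,0.198303
93,female,0.192229
93,male,0.223580
94,female,0.220135
94,male,0.252078
95,female,0.252091
95,male,0.284209
96,female,0.288687
96,male,0.320436
97,female,0.330596
97,male,0.361279
98,female,0.378588
98,male,0.407330
99,female,0.433547
99,male,0.459249
100,female,1.000000
100,male,1.000000
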