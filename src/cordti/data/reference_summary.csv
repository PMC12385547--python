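scanner,metric,region,n,test_mean,test_sd,test_ci_lo,test_ci_hi,retest_mean,retest_sd,retest_ci_lo,retest_ci_hi,pooled_mean,pooled_sd,pooled_ci_lo,pooled_ci_hi,p,diff_mean,diff_sd,diff_ci_lo,diff_ci_hi,loa_lo,loa_hi,cv_pct,icc_single,icc_single_lo,icc_single_hi,icc_average,icc_average_lo,icc_average_hi
skyra,fa,PT,16,0.578,0.031,0.562,0.595,0.581,0.023,0.569,0.593,0.580,0.025,0.567,0.593,0.636,-0.003,0.023,-0.015,0.010,-0.048,0.042,4.6,0.652,0.243,0.863,0.789,0.391,0.927
skyra,fa,DC,16,0.603,0.023,0.591,0.615,0.607,0.026,0.594,0.621,0.605,0.023,0.593,0.617,0.337,-0.004,0.017,-0.013,0.005,-0.038,0.029,4.0,0.751,0.433,0.905,0.858,0.604,0.950
skyra,fa,AH,16,0.417,0.037,0.397,0.437,0.411,0.034,0.393,0.429,0.414,0.033,0.396,0.432,0.372,0.006,0.027,-0.008,0.020,-0.046,0.058,8.6,0.726,0.384,0.894,0.841,0.555,0.944
skyra,rd,PT,16,0.415,0.076,0.374,0.455,0.410,0.065,0.375,0.444,0.412,0.061,0.380,0.444,0.791,0.005,0.074,-0.034,0.044,-0.140,0.150,17.2,0.472,-0.032,0.780,0.642,-0.067,0.876
skyra,rd,DC,16,0.351,0.056,0.321,0.381,0.340,0.075,0.300,0.380,0.345,0.060,0.314,0.377,0.489,0.010,0.058,-0.021,0.041,-0.104,0.124,19.0,0.624,0.205,0.850,0.769,0.340,0.919
skyra,rd,AH,16,0.649,0.067,0.613,0.684,0.643,0.078,0.601,0.684,0.646,0.064,0.612,0.680,0.726,0.006,0.070,-0.031,0.044,-0.131,0.144,11.2,0.550,0.079,0.817,0.709,0.146,0.899
skyra,md,PT,16,1.131,0.064,1.097,1.165,1.130,0.072,1.091,1.169,1.130,0.052,1.102,1.158,0.977,0.001,0.087,-0.046,0.047,-0.170,0.171,6.0,0.194,-0.357,0.627,0.324,-1.111,0.771
skyra,md,DC,16,1.119,0.065,1.084,1.154,1.117,0.083,1.072,1.161,1.118,0.066,1.083,1.153,0.900,0.002,0.069,-0.035,0.039,-0.133,0.137,6.6,0.592,0.138,0.837,0.744,0.243,0.911
skyra,md,AH,16,1.064,0.065,1.030,1.099,1.038,0.072,0.999,1.076,1.051,0.054,1.022,1.080,0.222,0.027,0.083,-0.018,0.071,-0.137,0.190,6.5,0.253,-0.232,0.649,0.403,-0.604,0.787
skyra,ad,PT,16,2.561,0.165,2.473,2.649,2.571,0.167,2.482,2.660,2.566,0.147,2.488,2.645,0.792,-0.010,0.154,-0.092,0.072,-0.312,0.291,6.5,0.586,0.132,0.834,0.739,0.233,0.910
skyra,ad,DC,16,2.655,0.206,2.545,2.765,2.670,0.195,2.566,2.773,2.662,0.191,2.561,2.764,0.640,-0.015,0.126,-0.082,0.052,-0.261,0.231,7.5,0.812,0.541,0.930,0.896,0.702,0.964
skyra,ad,AH,16,1.893,0.148,1.814,1.972,1.831,0.128,1.763,1.899,1.862,0.118,1.799,1.925,0.104,0.063,0.145,-0.015,0.140,-0.221,0.346,7.4,0.425,-0.026,0.745,0.596,-0.053,0.854
prisma,fa,PT,16,0.587,0.024,0.574,0.600,0.585,0.020,0.575,0.596,0.586,0.020,0.576,0.597,0.742,0.002,0.019,-0.009,0.012,-0.036,0.040,3.8,0.630,0.203,0.854,0.773,0.337,0.921
prisma,fa,DC,16,0.610,0.023,0.598,0.622,0.611,0.020,0.600,0.622,0.611,0.019,0.600,0.621,0.878,-0.001,0.019,-0.011,0.010,-0.038,0.037,3.5,0.610,0.167,0.845,0.758,0.287,0.916
prisma,fa,AH,16,0.407,0.039,0.386,0.428,0.400,0.036,0.381,0.420,0.404,0.033,0.386,0.421,0.459,0.007,0.036,-0.012,0.026,-0.064,0.077,9.3,0.549,0.093,0.815,0.709,0.170,0.898
prisma,rd,PT,16,0.405,0.072,0.367,0.443,0.418,0.063,0.384,0.452,0.411,0.060,0.380,0.443,0.439,-0.013,0.064,-0.047,0.022,-0.139,0.113,16.4,0.553,0.100,0.817,0.712,0.182,0.899
prisma,rd,DC,16,0.351,0.071,0.314,0.389,0.345,0.064,0.311,0.379,0.348,0.058,0.317,0.379,0.720,0.006,0.069,-0.030,0.043,-0.128,0.140,19.4,0.498,0.006,0.793,0.665,0.011,0.884
prisma,rd,AH,16,0.664,0.091,0.615,0.712,0.681,0.061,0.649,0.714,0.673,0.062,0.639,0.706,0.455,-0.018,0.091,-0.066,0.031,-0.197,0.162,11.3,0.307,-0.212,0.688,0.469,-0.539,0.815
prisma,md,PT,16,1.158,0.066,1.123,1.193,1.182,0.056,1.152,1.212,1.170,0.053,1.142,1.198,0.141,-0.024,0.061,-0.056,0.009,-0.143,0.096,5.2,0.483,0.036,0.778,0.651,0.069,0.875
prisma,md,DC,16,1.171,0.059,1.140,1.202,1.169,0.060,1.138,1.201,1.170,0.047,1.145,1.195,0.933,0.002,0.073,-0.038,0.041,-0.142,0.146,5.1,0.245,-0.305,0.657,0.393,-0.877,0.793
prisma,md,AH,16,1.069,0.085,1.023,1.114,1.086,0.054,1.057,1.115,1.078,0.056,1.048,1.107,0.438,-0.018,0.088,-0.064,0.029,-0.190,0.155,6.5,0.247,-0.274,0.653,0.396,-0.753,0.790
prisma,ad,PT,16,2.666,0.136,2.593,2.738,2.710,0.114,2.649,2.771,2.688,0.119,2.624,2.751,0.042,-0.044,0.080,-0.087,-0.002,-0.200,0.112,4.6,0.760,0.406,0.912,0.864,0.578,0.954
prisma,ad,DC,16,2.812,0.125,2.745,2.878,2.818,0.131,2.749,2.888,2.815,0.114,2.754,2.876,0.822,-0.007,0.115,-0.068,0.055,-0.232,0.218,4.5,0.610,0.169,0.845,0.758,0.289,0.916
prisma,ad,AH,16,1.880,0.126,1.812,1.947,1.897,0.133,1.827,1.968,1.888,0.113,1.828,1.948,0.592,-0.018,0.128,-0.086,0.051,-0.268,0.233,6.9,0.524,0.048,0.804,0.688,0.092,0.892
interscanner,fa,PT,16,0.580,0.025,0.567,0.593,0.586,0.020,0.576,0.597,,,,,0.104,-0.007,0.015,-0.015,0.002,-0.036,0.023,3.8,0.755,0.432,0.907,0.860,0.603,0.951
interscanner,fa,DC,16,0.605,0.023,0.593,0.617,0.611,0.019,0.600,0.621,,,,,0.219,-0.006,0.017,-0.015,0.004,-0.039,0.028,3.4,0.653,0.268,0.862,0.790,0.422,0.926
interscanner,fa,AH,16,0.414,0.033,0.396,0.432,0.404,0.033,0.386,0.421,,,,,0.239,0.010,0.033,-0.008,0.028,-0.055,0.075,8.1,0.493,0.037,0.785,0.661,0.071,0.880
interscanner,rd,PT,16,0.412,0.061,0.380,0.444,0.411,0.060,0.380,0.443,,,,,0.924,0.001,0.032,-0.017,0.018,-0.063,0.064,14.6,0.863,0.649,0.950,0.926,0.787,0.974
interscanner,rd,DC,16,0.345,0.060,0.314,0.377,0.348,0.058,0.317,0.379,,,,,0.820,-0.003,0.046,-0.027,0.022,-0.093,0.087,17.0,0.709,0.337,0.888,0.830,0.505,0.941
interscanner,rd,AH,16,0.646,0.064,0.612,0.680,0.673,0.062,0.639,0.706,,,,,0.092,-0.027,0.060,-0.059,0.005,-0.144,0.090,9.6,0.518,0.083,0.796,0.683,0.152,0.886
interscanner,md,PT,16,1.130,0.052,1.102,1.158,1.170,0.053,1.142,1.198,,,,,0.021,-0.040,0.062,-0.073,-0.007,-0.161,0.081,4.6,0.255,-0.145,0.628,0.407,-0.339,0.771
interscanner,md,DC,16,1.118,0.066,1.083,1.153,1.170,0.047,1.145,1.195,,,,,0.003,-0.052,0.059,-0.084,-0.021,-0.168,0.063,4.9,0.341,-0.093,0.694,0.509,-0.206,0.819
interscanner,md,AH,16,1.051,0.054,1.022,1.080,1.078,0.056,1.048,1.107,,,,,0.095,-0.027,0.060,-0.059,0.005,-0.144,0.091,5.2,0.382,-0.069,0.720,0.552,-0.149,0.837
interscanner,ad,PT,16,2.566,0.147,2.488,2.645,2.688,0.119,2.624,2.751,,,,,0.011,-0.122,0.168,-0.211,-0.032,-0.450,0.207,5.1,0.158,-0.186,0.540,0.273,-0.457,0.702
interscanner,ad,DC,16,2.662,0.191,2.561,2.764,2.815,0.114,2.754,2.876,,,,,0.002,-0.153,0.164,-0.240,-0.066,-0.473,0.168,5.6,0.318,-0.104,0.677,0.482,-0.232,0.807
interscanner,ad,AH,16,1.862,0.118,1.799,1.925,1.888,0.113,1.828,1.948,,,,,0.439,-0.026,0.132,-0.097,0.044,-0.285,0.233,6.1,0.349,-0.163,0.712,0.518,-0.389,0.832
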