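locus,kit,species,Na,Ho,He,Fis,hwe_p,PE,CumPE
Pma036,kit-1,P_leopardus,43,0.800,0.934,0.144,<0.001,0.768,0.768
Pma043,kit-1,P_leopardus,20,0.800,0.787,-0.017,0.953,0.419,0.865
Pma097,kit-1,P_leopardus,17,0.853,0.857,0.005,<0.001,0.553,0.940
Pma104,kit-1,P_leopardus,20,0.772,0.782,0.013,0.993,0.439,0.966
Pma106,kit-1,P_leopardus,25,0.902,0.928,0.029,0.893,0.747,0.991
Pma109,kit-1,P_leopardus,31,0.614,0.950,0.354,<0.001,0.817,0.998
Pma112,kit-1,P_leopardus,15,0.607,0.854,0.289,<0.001,0.555,0.999
Pma114,kit-1,P_leopardus,7,0.551,0.532,-0.036,0.198,0.146,0.999
Pma180,kit-1,P_leopardus,19,0.758,0.777,0.024,0.497,0.439,1.000
Ple002,kit-2,P_leopardus,21,0.877,0.868,-0.010,0.278,0.587,0.587
Ple004,kit-2,P_leopardus,16,0.747,0.759,0.015,0.754,0.402,0.753
Pma012,kit-2,P_leopardus,14,0.867,0.854,-0.015,0.256,0.541,0.887
Pma025,kit-2,P_leopardus,19,0.765,0.774,0.012,0.991,0.426,0.935
Pma038,kit-2,P_leopardus,23,0.891,0.882,-0.010,0.409,0.619,0.975
Pma090,kit-2,P_leopardus,10,0.460,0.472,0.025,0.391,0.113,0.978
Pma101,kit-2,P_leopardus,10,0.691,0.728,0.051,0.375,0.329,0.985
Pma412,kit-2,P_leopardus,9,0.632,0.657,0.039,0.147,0.270,0.989
Ple001,kit-3,P_leopardus,21,0.853,0.903,0.055,0.411,0.673,0.673
Ple005,kit-3,P_leopardus,14,0.782,0.808,0.032,0.077,0.467,0.826
Pma020,kit-3,P_leopardus,23,0.895,0.883,-0.014,0.510,0.620,0.934
Pma022,kit-3,P_leopardus,14,0.600,0.616,0.027,0.934,0.237,0.949
Pma027,kit-3,P_leopardus,23,0.895,0.865,-0.034,0.730,0.586,0.979
Pma121,kit-3,P_leopardus,15,0.825,0.875,0.057,0.256,0.594,0.992
Pma191,kit-3,P_leopardus,10,0.042,0.042,-0.012,1.000,0.001,0.992
Pma288,kit-3,P_leopardus,9,0.604,0.630,0.042,0.020,0.224,0.993
Pma036,kit-1,P_maculatus,59,0.961,0.957,-0.005,0.742,0.842,0.842
Pma043,kit-1,P_maculatus,20,0.807,0.839,0.038,0.092,0.536,0.927
Pma097,kit-1,P_maculatus,25,0.888,0.887,-0.001,0.651,0.638,0.973
Pma104,kit-1,P_maculatus,40,0.912,0.924,0.013,0.812,0.736,0.993
Pma106,kit-1,P_maculatus,17,0.839,0.871,0.038,0.927,0.595,0.997
Pma109,kit-1,P_maculatus,17,0.811,0.807,-0.004,0.452,0.480,0.999
Pma112,kit-1,P_maculatus,14,0.646,0.785,0.178,<0.001,0.422,0.999
Pma114,kit-1,P_maculatus,16,0.828,0.815,-0.016,0.012,0.489,1.000
Pma180,kit-1,P_maculatus,18,0.751,0.759,0.010,0.368,0.415,1.000
Ple002,kit-2,P_maculatus,14,0.860,0.854,-0.007,0.965,0.548,0.548
Ple004,kit-2,P_maculatus,11,0.744,0.740,-0.005,0.172,0.350,0.706
Pma012,kit-2,P_maculatus,10,0.681,0.716,0.049,0.361,0.318,0.800
Pma025,kit-2,P_maculatus,22,0.902,0.908,0.007,0.651,0.686,0.937
Pma038,kit-2,P_maculatus,20,0.916,0.891,-0.027,0.743,0.649,0.978
Pma090,kit-2,P_maculatus,10,0.758,0.740,-0.025,0.429,0.358,0.986
Pma101,kit-2,P_maculatus,15,0.709,0.683,-0.038,0.460,0.305,0.990
Pma412,kit-2,P_maculatus,9,0.656,0.640,-0.025,0.546,0.246,0.993
Ple001,kit-3,P_maculatus,20,0.793,0.765,-0.036,0.736,0.416,0.416
Ple005,kit-3,P_maculatus,8,0.698,0.662,-0.055,0.820,0.240,0.556
Pma020,kit-3,P_maculatus,20,0.916,0.892,-0.027,0.758,0.649,0.844
Pma022,kit-3,P_maculatus,9,0.740,0.741,0.001,0.903,0.358,0.900
Pma027,kit-3,P_maculatus,25,0.839,0.858,0.023,0.970,0.569,0.957
Pma121,kit-3,P_maculatus,15,0.796,0.760,-0.048,0.060,0.384,0.973
Pma191,kit-3,P_maculatus,12,0.856,0.859,0.003,0.313,0.555,0.988
Pma288,kit-3,P_maculatus,10,0.604,0.567,-0.065,0.586,0.180,0.990
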