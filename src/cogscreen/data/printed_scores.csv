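impaired,composite3,pd_composite3_rf,ssho2d,pd_ssho2d_linear,composite5,pd_composite5_linear,pd_f16,age,gender,income,education,race
0,0.597,0,0.229,0,0.92,0,0,77,F,8,9,W
0,0.513,0,0.899,0,0.639,0,0,78,F,9,11,W
0,0.564,0,0.473,0,0.791,0,0,80,M,7,8,W
0,0.562,0,0.51,0,0.611,0,0,75,F,9,8,W
0,0.546,0,0.703,0,0.798,0,0,75,F,4,6,W
0,0.507,0,0.897,0,0.358,0,0,67,F,5,8,W
0,0.618,0,-0.117,1,0.862,0,0,75,F,6,9,A
0,0.561,0,0.776,0,0.882,0,0,88,F,7,777,B
0,0.519,0,0.567,0,0.834,0,0,67,F,8,6,W
0,0.557,0,0.523,0,0.582,0,0,79,M,9,11,W
0,0.56,0,0.769,0,0.831,0,0,86,F,8,8,W
0,0.53,0,0.698,0,0.765,0,0,71,M,9,9,W
0,0.606,0,0.027,0,0.898,0,0,77,F,6,8,W
0,0.487,0,1.017,0,0.466,0,0,70,M,8,8,W
0,0.597,0,0.14,0,0.875,0,0,79,F,8,9,W
0,0.585,0,0.157,0,0.624,0,0,74,F,8,4,W
0,0.596,0,0.036,0,0.855,0,0,69,F,9,9,B
0,0.605,0,0.125,0,0.86,0,1,84,M,9,9,W
0,0.618,0,0.125,0,0.92,0,0,83,M,9,8,W
0,0.551,0,0.347,0,0.843,0,0,68,F,6,7,W
0,0.572,0,0.377,0,0.603,0,0,74,F,9,9,W
0,0.604,0,0.256,0,0.88,0,0,87,F,D,9,W
0,0.6,0,0.281,0,0.933,1,0,81,M,8,9,W
0,0.575,0,0.331,0,0.859,0,0,77,M,8,9,W
0,0.617,0,0.135,0,0.956,1,0,90,M,8,11,W
0,0.601,0,0.144,0,0.9,0,0,78,M,7,6,W
0,0.607,0,0.017,0,0.914,0,0,75,F,9,9,W
0,0.583,0,0.415,0,0.856,0,0,83,F,4,8,B
1,0.56,1,0.386,0,0.843,0,1,68,F,8,8,A
1,0.581,1,0.365,0,0.891,0,1,83,M,9,10,W
1,0.553,1,0.612,0,0.57,0,1,78,F,6,4,W
1,0.566,1,0.53,0,0.808,0,1,76,M,7,9,W
1,0.581,1,0.446,0,0.835,0,1,86,F,2,8,W
1,0.52,1,1.028,0,0.539,0,1,76,F,9,10,A
1,0.56,1,0.617,0,0.776,0,1,85,F,8,9,W
1,0.548,1,0.421,0,0.664,0,1,67,F,3,7,B
1,0.681,1,-0.737,1,0.958,1,1,80,F,6,6,W
1,0.644,1,0.022,0,0.963,1,0,93,F,5,4,W
1,0.619,0,-0.045,1,0.957,1,0,84,F,6,8,W
1,0.567,1,0.503,0,0.896,0,1,78,F,6,6,B
1,0.63,1,0.007,0,0.943,1,1,90,F,3,8,W
1,0.603,1,0.187,0,0.778,0,1,79,F,8,8,W
1,0.584,1,0.173,0,0.9,0,1,72,M,9,8,W
1,0.646,1,-0.327,1,0.847,0,1,81,F,5,4,W
1,0.633,1,-0.072,1,0.944,1,1,84,F,5,8,B
1,0.664,1,-0.57,1,0.946,1,1,75,M,7,4,W
1,0.63,1,-0.185,1,0.927,1,1,72,M,3,6,W
0,0.522,1,0.734,0,0.756,0,0,70,F,8,9,B
0,0.478,0,1.382,0,0.344,0,0,79,F,9,9,W
0,0.539,0,0.799,0,0.693,0,0,70,F,8,9,W
0,0.534,0,0.667,0,0.737,0,0,68,F,8,9,B
0,0.543,0,0.751,0,0.761,0,0,77,M,6,10,W
0,0.546,0,0.679,0,0.731,0,0,80,F,7,8,W
0,0.57,1,0.632,0,0.874,0,0,80,M,9,9,B
0,0.51,0,0.907,0,0.545,0,0,70,M,9,9,W
0,0.546,0,0.659,0,0.79,0,0,74,F,8,8,W
0,0.53,0,0.847,0,0.713,0,0,72,F,9,8,W
0,0.454,0,1.399,0,0.262,0,0,71,F,7,9,W
0,0.51,0,0.914,0,0.605,0,0,75,F,6,9,W
0,0.548,1,0.668,0,0.831,0,0,73,F,7,11,W
0,0.552,0,0.527,0,0.882,0,0,75,M,9,9,W
0,0.473,0,1.362,0,0.311,0,0,76,F,8,9,W
0,0.544,0,1.017,0,0.693,0,0,83,F,2,6,W
0,0.508,0,1.029,0,0.515,0,0,74,F,9,9,W
0,0.465,0,1.393,0,0.291,0,0,74,F,5,8,W
0,0.584,0,0.317,0,0.581,0,0,83,F,9,9,W
0,0.503,0,1.03,0,0.339,0,0,78,F,9,8,W
0,0.538,0,0.696,0,0.455,0,0,75,F,4,6,W
0,0.462,0,1.207,0,0.255,0,0,70,F,7,6,W
0,0.53,0,0.617,0,0.747,0,0,69,M,5,6,W
0,0.535,0,0.756,0,0.769,0,0,78,F,9,9,W
0,0.486,0,1.195,0,0.389,0,0,70,F,8,9,W
0,0.537,0,0.833,0,0.769,0,0,78,F,8,10,W
0,0.51,0,0.784,0,0.672,0,0,68,F,7,9,B
0,0.523,0,0.682,0,0.536,0,0,69,F,8,8,W
0,0.544,0,0.563,0,0.817,0,0,71,M,9,9,W
0,0.484,0,1.147,0,0.237,0,0,68,F,7,8,W
0,0.494,0,1.015,0,0.478,0,0,71,F,9,9,B
0,0.546,0,0.564,0,0.824,0,0,72,M,7,777,W
0,0.565,0,0.616,0,0.863,0,0,78,M,9,10,W
0,0.544,0,0.477,0,0.876,0,0,74,M,6,8,A
0,0.459,0,1.46,0,0.226,0,0,67,F,9,11,W
0,0.506,0,0.986,0,0.581,0,0,73,F,5,9,W
0,0.524,0,1.002,0,0.672,0,0,81,M,5,9,U
0,0.479,0,1.13,0,0.389,0,0,70,F,8,7,W
0,0.548,0,0.584,0,0.879,0,0,81,M,9,11,W
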