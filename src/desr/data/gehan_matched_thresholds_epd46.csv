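r_alt,r_nul,epd_alt,epd_nul,n1,n2,s_r,s_p,a_r,a_p,power,alpha,en_nul,pes_nul,en_alt,pes_alt
0.2,0.05,0.4,0.6,14,1,1,8,2,7,0.835,0.089,14.1,0.89,14.9,0.14
0.2,0.05,0.4,0.6,14,3,1,8,2,9,0.855,0.101,14.3,0.89,17.0,0.008
0.2,0.05,0.4,0.6,14,4,1,8,3,9,0.797,0.051,14.4,0.89,17.4,0.14
0.2,0.05,0.4,0.6,14,5,1,8,3,9,0.787,0.041,14.6,0.89,18.3,0.14
0.2,0.05,0.4,0.6,14,6,1,8,3,9,0.776,0.034,14.7,0.89,19.2,0.14
0.2,0.05,0.4,0.6,14,9,1,8,3,11,0.814,0.04,15.0,0.89,21.7,0.14
0.2,0.05,0.4,0.6,14,10,1,8,3,12,0.829,0.046,15.1,0.89,23.9,0.008
0.2,0.05,0.4,0.6,14,11,1,8,4,12,0.779,0.035,15.2,0.89,24.9,0.008
0.2,0.05,0.4,0.6,14,13,1,8,4,14,0.817,0.032,15.4,0.89,25.2,0.14
0.2,0.05,0.4,0.6,14,15,1,8,4,14,0.807,0.032,15.7,0.89,26.9,0.14
0.2,0.05,0.4,0.6,14,16,1,8,4,14,0.8,0.027,15.8,0.89,27.8,0.14
0.2,0.05,0.4,0.6,14,18,1,8,4,16,0.829,0.026,16.0,0.89,29.5,0.14
0.2,0.05,0.4,0.6,14,20,1,8,5,17,0.809,0.0174,16.2,0.89,31.2,0.14
0.2,0.05,0.4,0.6,14,21,1,8,5,17,0.804,0.021,16.3,0.89,32.0,0.14
0.2,0.05,0.4,0.6,14,22,1,8,5,19,0.83,0.024,16.4,0.89,32.9,0.14
0.2,0.05,0.4,0.6,14,23,1,8,5,19,0.828,0.02,16.5,0.89,33.8,0.14
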