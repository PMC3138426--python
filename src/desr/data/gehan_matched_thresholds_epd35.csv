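r_alt,r_nul,epd_alt,epd_nul,n1,n2,s_r,s_p,a_r,a_p,power,alpha,en_nul,pes_nul,en_alt,pes_alt
0.2,0.05,0.3,0.5,14,1,1,6,2,5,0.811,0.075,14.1,0.91,14.8,0.17
0.2,0.05,0.3,0.5,14,3,1,6,3,7,0.773,0.043,14.3,0.91,16.5,0.17
0.2,0.05,0.3,0.5,14,4,1,6,3,7,0.775,0.038,14.3,0.91,17.3,0.17
0.2,0.05,0.3,0.5,14,5,1,6,3,7,0.773,0.034,14.4,0.92,18.2,0.17
0.2,0.05,0.3,0.5,14,6,1,6,3,7,0.769,0.031,14.5,0.91,19.0,0.17
0.2,0.05,0.3,0.5,14,9,1,6,3,9,0.805,0.038,14.8,0.91,21.5,0.17
0.2,0.05,0.3,0.5,14,10,1,6,4,9,0.753,0.026,14.9,0.91,22.3,0.17
0.2,0.05,0.3,0.5,14,11,1,6,3,9,0.797,0.033,14.9,0.91,23.2,0.17
0.2,0.05,0.3,0.5,14,13,1,6,4,11,0.791,0.023,15.1,0.91,24.8,0.17
0.2,0.05,0.3,0.5,14,15,1,6,4,11,0.789,0.024,15.3,0.91,26.5,0.17
0.2,0.05,0.3,0.5,14,16,1,6,4,11,0.787,0.028,15.4,0.91,27.3,0.17
0.2,0.05,0.3,0.5,14,18,1,6,4,13,0.811,0.023,15.5,0.91,29.0,0.17
0.2,0.05,0.3,0.5,14,20,1,6,5,13,0.781,0.015,15.7,0.91,30.7,0.17
0.2,0.05,0.3,0.5,14,21,1,6,5,13,0.779,0.013,15.8,0.91,31.5,0.17
0.2,0.05,0.3,0.5,14,22,1,6,5,15,0.803,0.016,15.9,0.91,32.3,0.17
0.2,0.05,0.3,0.5,14,23,1,6,5,15,0.804,0.014,16.0,0.91,33.2,0.17
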