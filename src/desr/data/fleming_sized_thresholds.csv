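r_alt,r_nul,epd_alt,epd_nul,n1,n2,s_r,s_p,a_r,a_p,power,alpha,en_nul,pes_nul,en_alt,pes_alt
0.2,0.05,0.4,0.6,15,15,1,8,4,14,0.796,0.025,16.4,0.90,27.7,0.15
0.2,0.05,0.3,0.5,15,15,1,6,4,11,0.785,0.025,16.2,0.92,27.4,0.17
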