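trial_id,n1,r1,p1,n_tot,r_tot,p_tot,investigator_stopped
1,15,0,6,,,,false
2,15,0,1,,,,false
3,15,0,10,,,,false
4,15,0,7,,,,false
5,15,0,9,,,,false
6,15,0,14,,,,false
7,14,0,7,,,,false
8,15,0,6,,,,false
9,15,0,3,,,,false
10,15,0,12,,,,false
11,15,1,9,,,,true
12,15,7,6,30,13,13,false
13,15,1,6,25,1,12,false
14,15,1,6,30,3,13,false
15,15,2,4,30,2,8,false
16,15,1,6,29,4,12,false
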