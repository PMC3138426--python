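trial_id,n1,r1,p1,n_tot,r_tot,p_tot,investigator_stopped
1,14,0,14,23,0,20,false
2,14,0,10,24,0,18,false
3,14,0,9,17,0,10,false
4,14,0,8,36,0,23,false
5,14,0,11,19,0,14,false
6,14,0,13,23,0,20,false
7,14,0,11,15,0,12,false
8,14,0,11,,,,false
9,14,1,12,34,2,23,false
10,14,1,8,27,2,16,false
11,14,1,10,19,1,12,false
12,14,1,10,25,2,17,false
13,14,1,10,20,1,15,false
14,14,1,9,17,1,11,false
15,14,1,12,18,1,16,false
16,14,4,9,29,7,14,false
17,14,8,2,34,20,3,false
18,14,5,4,32,7,13,false
19,14,4,4,37,12,14,false
20,14,4,3,30,7,11,false
21,14,5,4,36,9,9,false
22,14,3,4,27,6,10,false
23,14,11,1,35,27,3,false
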