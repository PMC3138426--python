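trial_id,gehan_stop,desr46_stop,desr35_stop,gehan_activity,desr46_activity,desr35_activity
1,Y,Y,Y,N,N,N
2,Y,Y,Y,N,N,N
3,Y,Y,Y,N,N,N
4,Y,Y,Y,N,N,N
5,Y,Y,Y,N,N,N
6,Y,Y,Y,N,N,N
7,Y,Y,Y,N,N,N
8,Y,Y,Y,N,N,N
9,N,Y,Y,N,N,N
10,N,Y,Y,N,N,N
11,N,Y,Y,N,N,N
12,N,Y,Y,N,N,N
13,N,Y,Y,N,N,N
14,N,Y,Y,N,N,N
15,N,Y,Y,N,N,N
16,N,N,N,Y,Y,Y
17,N,N,N,Y,Y,Y
18,N,N,N,Y,Y,Y
19,N,N,N,Y,Y,Y
20,N,N,N,Y,Y,Y
21,N,N,N,Y,Y,Y
22,N,N,N,Y,Y,Y
23,N,N,N,Y,Y,Y
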