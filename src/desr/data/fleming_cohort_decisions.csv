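trial_id,fleming_stop,desr46_stop,desr35_stop,fleming_activity,desr46_activity,desr35_activity
1,Y,N,Y,N,P,N
2,Y,N,N,N,P,P
3,Y,Y,Y,N,N,N
4,Y,N,Y,N,P,N
5,Y,Y,Y,N,N,N
6,Y,Y,Y,N,N,N
7,Y,N,Y,N,P,N
8,Y,N,Y,N,P,N
9,Y,N,N,N,P,P
10,Y,Y,Y,N,N,N
11,N,Y,Y,?,N,N
12,N,N,N,Y,Y,Y
13,N,N,Y,N,Y,N
14,N,N,Y,N,Y,N
15,N,N,N,N,Y,Y
16,N,N,Y,Y,Y,N
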