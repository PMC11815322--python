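age,sex,qx
50,male,0.0032
51,male,0.0035118775528578624
52,male,0.0038541512332084154
53,male,0.004229783500382526
54,male,0.004642025540138109
55,male,0.005094445404438724
56,male,0.005590958893783828
57,male,0.006135863449384516
58,male,0.00673387534852953
59,male,0.0073901705250761784
60,male,0.008110429368377135
61,male,0.008900885888388384
62,male,0.0097683816724939
63,male,0.010720425101056086
64,male,0.011765256334216516
65,male,0.012911918632423051
66,male,0.01417033662797928
67,male,0.015551402225075001
68,male,0.01706706887178272
69,male,0.018730455019966532
70,male,0.020555957668573228
71,male,0.022559376973049616
72,male,0.024758052999409835
73,male,0.02717101580659146
74,male,0.02981915015609836
75,male,0.032725376274531204
76,male,0.03591484823354794
77,male,0.039415171664279325
78,male,0.043256642690569315
79,male,0.047472510149063604
80,male,0.05209926336572297
81,male,0.057176947979535146
82,male,0.06274951254695349
83,male,0.06886518892700587
84,male,0.07557690973939615
85,male,0.08294276650879691
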