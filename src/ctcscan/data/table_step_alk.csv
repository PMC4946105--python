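cell_id,0.5,0.6,0.7,0.8
1,16,16,16,16
2,16,16,16,16
3,32,32,32,28
4,32,32,28,27
5,16,16,14,13
6,32,32,32,32
7,14,14,14,14
8,13,16,12,16
9,29,28,32,32
10,16,16,16,16
11,16,16,16,16
12,28,26,31,31
13,32,32,32,30
14,32,32,32,32
15,14,14,14,14
16,27,28,18,27
17,16,16,16,16
18,14,14,14,12
19,30,32,30,27
20,16,16,16,14
21,16,16,16,16
22,32,32,31,22
23,32,32,27,24
24,32,32,32,32
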