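cell_id,5,10,15,20,25,30
1,5,9,2,10,16,22
2,23,32,22,32,33,36
3,4,12,6,15,16,16
4,11,20,10,24,30,32
5,10,6,12,16,14,16
6,26,14,2,30,31,45
7,3,44,2,39,59,59
8,15,4,4,27,31,31
9,14,8,2,31,33,34
10,6,2,16,26,26,31
11,2,2,4,15,16,22
12,14,32,2,60,58,61
13,13,0,20,28,28,28
14,10,10,12,35,32,35
15,17,10,10,56,53,65
16,16,6,8,28,30,32
17,6,6,10,14,15,16
18,5,14,2,14,14,20
19,8,4,6,16,26,31
20,30,20,26,52,52,44
21,4,16,6,12,18,27
22,7,n.i.,6,30,29,30
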