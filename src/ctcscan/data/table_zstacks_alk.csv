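cell_id,5,10,15,20,25,30
1,n.i.,9,9,13,10,18
2,3,8,6,16,15,16
3,n.i.,3,2,8,7,12
4,4,11,2,4,13,13
5,n.i.,5,6,8,8,17
6,n.i.,12,4,4,2,16
7,8,6,8,19,1,27
8,2,4,4,8,10,15
9,2,2,3,13,7,16
10,n.i.,2,26,14,17,27
11,n.i.,4,8,8,10,16
12,1,10,6,16,12,16
13,1,4,2,16,2,3
14,n.i.,6,9,14,14,14
15,2,4,n.i.,4,4,16
16,1,10,8,2,7,16
17,n.i.,6,9,8,20,9
18,6,7,7,16,14,16
19,6,7,n.i.,10,12,18
20,3,8,6,6,8,18
21,1,3,9,6,8,8
22,2,5,6,n.i.,14,8
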