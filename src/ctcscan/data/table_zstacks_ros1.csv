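cell_id,5,10,15,20,25,30
1,9,n.i.,6,14,14,30
2,4,10,10,10,10,10
3,12,22,18,28,28,28
4,3,2,n.i.,13,14,14
5,4,4,4,4,4,4
6,26,28,26,34,34,34
7,6,15,11,20,28,28
8,36,42,48,52,62,62
9,10,14,18,20,30,30
10,13,20,22,26,30,30
11,2,12,12,13,14,14
12,6,6,8,10,14,14
13,4,6,6,8,14,14
14,8,13,20,32,32,32
15,10,14,14,16,16,16
16,10,12,13,16,16,16
17,2,6,4,15,16,16
18,4,11,16,25,25,25
19,20,33,26,46,55,64
20,12,14,12,14,15,14
21,11,n.i.,20,24,28,28
22,10,12,12,20,19,12
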