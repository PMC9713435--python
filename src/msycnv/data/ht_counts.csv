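node,count
Tb-d,87
Ad,24
Tb-o,21
Ao,18
DW4,16
Tu,8
I,6
DW3,5
N,5
O,4
Hs,4
Y,3
Pa,2
Am,1
Ta,1
Tb,1
Tb-1,1
DW1,1
M,1
DW2,0
Pb,0
Crown,0
T,0
A,0
H,0
P,0
Root,0
DW4-u,0
Tb1-u,0
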