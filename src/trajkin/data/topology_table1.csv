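motion,child,parent
1,1,0
4,4,2
5,5,2
14,14,2
15,15,2
16,4,14
17,5,15
18,16,14
19,17,15
20,18,14
21,19,15
22,16,4
23,17,5
24,18,4
25,19,5
26,18,16
27,19,17
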