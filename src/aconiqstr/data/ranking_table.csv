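# Experimental-toxicity rank and per-receptor docking fit-score ranks (1 = best)
# for the 33 aconitine alkaloids against receptors 2V7O (CAMK2G) and 2VZ6 (CAMK2A).
id,exp_rank,fit_2V7O,fit_2VZ6
6,1,3,3
20,2,1,12
12,3,4,9
1,4,2,4
11,5,7,2
14,6,8,13
16,7,5,6
7,8,17,15
8,9,10,11
27,10,23,17
13,11,12,19
15,12,11,5
32,13,18,18
5,14,22,8
33,15,13,29
21,16,15,1
25,17,9,20
22,18,25,25
17,19,20,16
28,20,24,30
9,21,16,32
29,22,32,14
2,23,30,24
30,24,31,26
18,25,21,27
10,26,26,21
23,27,29,31
31,28,33,7
26,29,14,23
4,30,28,33
3,31,6,10
19,32,27,28
24,33,19,22
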