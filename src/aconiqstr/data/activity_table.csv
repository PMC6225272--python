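# Aconitine-alkaloid acute-toxicity dataset: 33 compounds, pLD50 (mice),
# substituent strings R1-R13 as metadata; is_test marks the 7 external-set compounds.
id,cas,substituents,pld50,is_test
1,302-27-2,methoxymethyl-hydroxy-methoxy-methoxy-H-acetoxyl-hydroxy-methoxy-benzoxy-H-hydroxy-H-ethyl,4.92,0
2,545-56-2,methoxymethyl-H-hydroxy-methoxy-hydroxy-hydroxy-H-methoxy-hydroxy-H-H-H-ethyl,1.96,1
3,127-29-7,"methoxymethyl-hydroxy-methoxy-methoxy-H-acetoxyl-H-methoxy-methyl 2,3-dimethoxybenzoate-H-hydroxy-H-ethyl",1.44,0
4,509-18-2,methoxymethyl-H-hydroxy-methoxy-hydroxy-hydroxy-H-methoxy-methoxy-H-H-H-ethyl,1.76,0
5,466-24-0,methoxymethyl-hydroxy-methoxy-methoxy-H-hydroxy-hydroxy-methoxy-benzoxy-H-hydroxy-H-ethyl,3.0,1
6,2752-64-9,methoxymethyl-hydroxy-methoxy-methoxy-H-acetoxyl-hydroxy-methoxy-benzoxy-H-hydroxy-H-methy,5.0,0
7,4491-19-4,methoxymethyl-hydroxy-methoxy-methoxy-H-acetoxyl-H-methoxy-benzoxy-H-hydroxy-H-ethyl,4.33,0
8,6900-87-4,methoxymethyl-H-methoxy-methoxy-H-acetoxyl-hydroxy-methoxy-benzoxy-H-hydroxy-H-methy,4.33,1
9,1356-52-1,H-H-methoxy-H-H-hydroxy-H-methoxy-benzoxy-H-H-hydroxy-H-ethyl,2.55,0
10,6836-11-9,methy-H-methoxy-acetoxyl-dioxolane-H-H-methoxy-methoxy-H-H-hydroxy-ethyl,1.88,0
11,8006-38-0,methoxymethyl-hydroxy-methoxy-methoxy-H-acetoxyl-hydroxy-methoxy-benzoxy-H-hydroxy-H-ethyl,4.78,0
12,20501-56-8,methoxymethyl-H-methoxy-H-H-hydroxy-H-methoxy-hydroxy-H-H-H-ethyl,4.94,1
13,21019-30-7,"2-(3-methyl-2,5-dioxopyrrolidin-1-yl)benzoate ethyl-H-methoxy-methoxy-hydroxy-hydroxy-H-methoxy-methoxy-H-H-H-ethyl",3.52,0
14,41849-35-8,methoxymethyl-hydroxy-methoxy-methoxy-H-acetoxyl-hydroxy-methoxy-benzoxy-H-hydroxy-hydroxy-ethyl,4.66,0
15,26000-16-8,"2-(3-methyl-2,5-dioxopyrrolidin-1-yl)benzoate ethyl-H-methoxy-methoxy-a-H-H-methoxy-methoxy-H-H-H-ethyl",3.3,0
16,77181-26-1,methoxymethyl-acetoxyl-methoxy-methoxy-H-acetoxyl-hydroxy-methoxy-benzoxy-H-hydroxy-H-ethyl,4.4,0
17,71402-60-3,methoxymethyl-hydroxy-methoxy-methoxy-H-hydroxy-hydroxy-methoxy-benzoxy-H-hydroxy-H-trimethylethanaminium,2.59,0
18,67806-02-4,methoxymethyl-acetoxyl-methoxy-methoxy-H-acetoxyl-acetoxyl-methoxy-benzoxy-H-acetoxyl-H-ethyl,1.9,0
19,85031-25-0,methoxymethyl-acetoxyl-methoxy-methoxy-H-acetoxyl-acetoxyl-methoxy-acetoxyl-H-acetoxyl-H-ethyl,1.17,0
20,71425-64-4,methoxymethyl-hydroxy-methoxy-methoxy-H-acetoxyl-hydroxy-methoxy-benzoxy-H-hydroxy-H-trimethylethanaminium,4.95,0
21,63238-67-5,methoxymethyl-hydroxy-methoxy-methoxy-H-hydroxy-hydroxy-methoxy-benzoxy-H-hydroxy-H-methy,2.68,1
22,71402-61-4,methoxymethyl-hydroxy-methoxy-methoxy-H-hydroxy-hydroxy-methoxy-benzoxy-hydroxy-H-H-trimethylethanaminium,2.62,0
23,38146-89-3,methoxymethyl-hydroxy-methoxy-methoxy-H-hydroxy-H-methoxy-hydroxy-H-hydroxy-H-ethyl,1.85,0
24,82144-73-8,methoxymethyl-acetoxyl-methoxy-methoxy-H-acetoxyl-H-methoxy-benzoxy-H-hydroxy-H-ethyl,0.84,0
25,82144-74-9,methoxymethyl-acetoxyl-methoxy-methoxy-H-acetoxyl-H-methoxy-benzoxy-H-acetoxyl-H-ethyl,2.66,0
26,38146-91-7,methoxymethyl-acetoxyl-methoxy-methoxy-H-acetoxyl-H-methoxy-acetoxyl-H-acetoxyl-H-ethyl,1.82,0
27,71402-59-0,methoxymethyl-H-methoxy-methoxy-H-acetoxyl-hydroxy-methoxy-benzoxy-H-hydroxy-H-ethyl,4.27,1
28,71402-62-5,methoxymethyl-H-hydroxy-methoxy-H-hydroxy-hydroxy-methoxy-benzoxy-H-hydroxy-H-methy,2.59,0
29,39089-30-0,methy-H-hydroxy-H-H-hydroxy-H-methoxy-hydroxy-H-H-H-ethyl,2.29,0
30,58111-33-4,methoxymethyl-H-hydroxy-methoxy-hydroxy-hydroxy-H-methoxy-H-methoxy-H-H-trimethylethanaminium,1.93,0
31,23943-93-3,hydroxy-H-methoxy-hydroxy-H-hydroxy-H-methoxy-methoxy-H-H-H-ethyl,1.85,1
32,32854-75-4,2-acetamidobenzoate ethyl-H-methoxy-H-H-hydroxy-H-methoxy-methoxy-hydroxy-H-H-ethyl,3.16,0
33,138729-51-8,2-acetamidobenzoate ethyl-H-methoxy-H-H-acetoxyl-H-methoxy-methoxy-acetoxyl-H-H-ethyl,2.84,0
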