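id,kernel,contrast_enhanced,tube_current_ma,voltage_kvp,cortical_median_hu,cancellous_median_hu,ng_class,lz_class
1,Soft tissue,no,178-635,80,458,45,4,4
2,Soft tissue,no,91-414,80,424,54,4,4
3,Soft tissue,no,18-82,100,307,24,4,4
4,Soft tissue,no,150-210,120,301,-2,4-additional,4
5,Soft tissue,no,123-214,100,381,74,4,4
6,Soft tissue,no,15-215,120,250,38,4,4
7,Soft tissue,yes,134-686,100,383,46,4,4
8,Soft tissue,yes,61-256,80,326,99,4,4
9,Soft tissue,yes,150 (fixed),120,215,18,4,4
10,Soft tissue,no,134-642,120,420,91,4,4
11,Soft tissue,yes,196-439,120,290,93,4,3
12,Soft tissue,yes,150 (fixed),120,250,43,4,4
13,Soft tissue,yes,48-200,80,376,68,4,4
14,Soft tissue,yes,145-644,90,378,45,4,4
15,Soft tissue,yes,151-220,100,287,49,4,4
16,Soft tissue,no,25-145,90,330,28,4,4
17,Soft tissue,yes,180-516,80,474,123,4,4
18,Soft tissue,no,108-633,100,337,118,4,4
19,Soft tissue,yes,50-115,120,264,42,4,4
20,Soft tissue,yes,150-155,120,250,59,4,4
21,Soft tissue,yes,86-745,80,342,58,4,4
22,Soft tissue,no,162-659,120,305,74,4,4
23,Soft tissue,yes,74-327,80,414,60,4,4
24,Soft tissue,yes,150 (fixed),120,239,60,4,4
25,Lung tissue,yes,61-120,120,347,51,4,4
26,Soft tissue,yes,142-417,80,389,27,4,4
27,Soft tissue,yes,150-402,120,287,78,4,4
28,Soft tissue,no,95-445,100,308,31,4,4
29,Soft tissue,yes,150-160,120,292,93,4,4
30,Soft tissue,no,47-379,120,257,55,4,4
31,Lung tissue,yes,153-380,120,354,77,4,4
32,Bone tissue,no,155-356,120,390,48,4,4
33,Soft tissue,yes,150 (fixed),120,387,134,4,4
34,Soft tissue,no,124-591,100,424,120,4,4
35,Soft tissue,no,49-250,90,451,76,4,4
36,Soft tissue,yes,150-180,120,237,16,4,4
37,Lung tissue,yes,50-227,80,447,64,4,4
38,Soft tissue,yes,120-341,120,270,43,4,4
39,Soft tissue,yes,150-361,120,311,41,4,4
40,Soft tissue,no,101-359,120,318,113,4,4
41,Soft tissue,yes,70-172,120,258,34,4,4
42,Soft tissue,yes,151-381,100,230,-12,4-additional,4
43,Soft tissue,yes,63-741,90,224,21,4,4
44,Soft tissue,no,194-396,100,347,135,4,4
45,Soft tissue,no,150-210,120,217,29,4,4
46,Soft tissue,yes,150 (fixed),120,329,77,4,4
47,Soft tissue,yes,150-175,120,183,10,4,4
48,Soft tissue,no,121-231,100,363,61,4,4
49,Soft tissue,yes,50-129,120,294,102,4,4
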