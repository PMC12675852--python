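id,height_mm,thickness_sl_mm,thickness_il_mm,width_sl_mm,width_il_mm,shape,stt_mm
1,43.0,12.0,6.5,53.5,50.5,trapezoid,12.8
2,57.6,13.2,9.6,48.2,53.5,trapezoid,10.7
3,46.6,12.3,9.5,50.9,51.8,trapezoid,20.0
4,53.8,12.8,9.2,55.4,60.5,trapezoid,17.6
5,46.8,11.5,7.5,54.8,53.7,trapezoid,14.4
6,45.6,13.6,8.4,54.8,44.5,trapezoid,17.7
7,47.2,14.0,11.3,52.7,59.2,trapezoid,33.0
8,53.8,15.4,9.4,54.0,56.4,triangular,17.4
9,50.6,12.2,7.7,47.2,58.1,trapezoid,13.5
10,46.1,12.2,7.9,48.9,63.4,trapezoid,20.0
11,45.5,13.3,9.5,49.1,55.9,trapezoid,40.8
12,59.5,14.2,11.2,51.1,68.5,quadrangular,11.7
13,56.2,12.0,7.3,60.9,52.8,triangular,12.9
14,59.4,15.3,11.5,49.7,59.2,trapezoid,47.3
15,47.6,11.4,7.6,45.4,50.2,quadrangular,22.3
16,58.3,12.6,9.0,50.4,58.8,trapezoid,9.4
17,57.1,13.9,9.6,40.4,65.5,quadrangular,23.1
18,45.5,13.6,10.2,59.7,61.0,trapezoid,8.6
19,54.6,14.6,10.1,50.0,59.8,trapezoid,7.8
20,49.5,12.9,9.5,70.1,68.8,trapezoid,14.9
21,58.5,17.1,13.3,74.5,71.5,quadrangular,13.9
22,49.9,13.4,8.4,50.7,59.4,trapezoid,38.2
23,46.8,13.2,9.4,56.4,72.1,triangular,11.1
24,47.0,13.1,7.3,50.5,58.8,quadrangular,15.0
25,50.9,15.5,10.6,51.8,57.4,quadrangular,14.3
26,50.7,10.6,6.6,45.1,56.3,quadrangular,7.4
27,63.4,12.7,8.2,54.6,61.6,quadrangular,19.5
28,51.7,10.9,7.3,49.5,45.1,quadrangular,29.0
29,47.1,11.4,7.2,49.6,58.9,quadrangular,10.3
30,62.9,15.3,6.4,61.9,58.5,quadrangular,22.0
31,53.4,12.0,8.7,46.4,66.7,trapezoid,27.4
32,50.4,13.5,11.3,62.1,55.2,triangular,23.5
33,49.3,12.5,7.3,45.8,57.3,quadrangular,12.7
34,56.5,13.8,7.8,70.1,61.0,trapezoid,22.4
35,58.3,12.4,9.4,46.8,57.4,quadrangular,18.7
36,54.4,14.8,10.5,63.1,61.7,quadrangular,4.4
37,57.5,14.0,9.3,53.1,53.1,trapezoid,21.0
38,50.4,13.5,11.0,58.5,57.1,quadrangular,7.4
39,69.1,15.4,10.0,61.6,51.7,quadrangular,27.7
40,52.0,15.3,9.0,64.9,60.1,trapezoid,7.9
41,53.0,12.2,7.7,45.9,44.1,quadrangular,15.3
42,49.4,10.4,6.7,66.5,54.0,trapezoid,8.6
43,48.2,12.5,6.9,56.3,48.7,trapezoid,19.2
44,41.6,11.0,7.3,44.1,46.2,trapezoid,10.7
45,56.5,17.2,8.4,37.6,61.3,trapezoid,15.7
46,48.2,9.7,7.6,36.8,49.4,quadrangular,6.8
47,48.0,13.2,8.4,53.8,53.1,quadrangular,16.4
48,47.8,12.7,7.4,56.9,59.7,trapezoid,9.8
49,51.0,11.0,6.1,44.5,47.6,trapezoid,12.4
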