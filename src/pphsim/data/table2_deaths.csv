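woman_id,cause_of_death,timing,took_misoprostol,place,attendant
1,pph,before,yes,home,skilled
2,pph,before,yes,home,skilled
3,pph,before,yes,home,skilled
4,pph,before,yes,home,skilled
5,pph,during,yes,home,skilled
6,pph,during,yes,home,skilled
7,pph,during,yes,home,skilled
8,pph,during,yes,home,skilled
9,pph,during,yes,home,skilled
10,pph,during,yes,home,skilled
11,pph,during,yes,home,skilled
12,pph,after,yes,home,skilled
13,pph,after,yes,home,skilled
14,pph,after,yes,home,skilled
15,pph,after,yes,home,skilled
16,pph,after,yes,home,skilled
17,pph,after,yes,home,skilled
18,pph,after,no,home,skilled
19,pph,after,no,home,skilled
20,pph,after,no,home,unskilled
21,pph,after,no,home,unskilled
22,pph,after,no,home,unskilled
23,pph,after,no,home,unskilled
24,pph,after,no,home,unskilled
25,pph,after,no,home,unskilled
26,pph,after,no,home,unskilled
27,pph,after,no,home,unskilled
28,pph,after,no,home,unskilled
29,pph,after,no,home,unskilled
30,pph,after,no,home,unskilled
31,pph,after,no,home,unskilled
32,pph,after,no,home,unskilled
33,pph,after,no,home,unskilled
34,pph,after,unknown,home,unskilled
35,pph,after,unknown,facility,unskilled
36,pph,after,unknown,facility,unskilled
37,pph,after,unknown,facility,unskilled
38,pph,after,unknown,facility,unskilled
39,pph,after,unknown,facility,unskilled
40,pph,after,unknown,facility,unskilled
41,pph,after,unknown,facility,unskilled
42,pph,after,unknown,facility,unskilled
43,pph,after,unknown,facility,unskilled
44,pph,after,unknown,facility,unskilled
45,pph,after,unknown,facility,unskilled
46,pph,after,unknown,facility,unskilled
47,pph,after,unknown,facility,unskilled
48,pph,after,unknown,facility,unskilled
49,pph,after,unknown,facility,unskilled
50,pph,after,unknown,unknown,unskilled
51,pph,after,unknown,unknown,unknown
52,pph,after,unknown,unknown,unknown
53,pph,after,unknown,unknown,unknown
54,pph,unknown,unknown,unknown,unknown
55,aph,before,yes,facility,skilled
56,aph,during,no,facility,unskilled
57,aph,during,no,unknown,unskilled
58,aph,during,no,unknown,unskilled
59,aph,after,no,unknown,unskilled
60,eclampsia,before,yes,home,skilled
61,eclampsia,before,yes,home,skilled
62,eclampsia,before,yes,home,skilled
63,eclampsia,before,no,home,skilled
64,eclampsia,before,no,facility,skilled
65,eclampsia,before,no,facility,skilled
66,eclampsia,before,no,facility,skilled
67,eclampsia,before,no,facility,skilled
68,eclampsia,before,no,facility,skilled
69,eclampsia,before,no,facility,skilled
70,eclampsia,before,no,facility,skilled
71,eclampsia,during,no,facility,unskilled
72,eclampsia,during,no,facility,unskilled
73,eclampsia,during,no,facility,unskilled
74,eclampsia,after,no,facility,unskilled
75,eclampsia,after,no,facility,unskilled
76,eclampsia,after,no,unknown,unskilled
77,eclampsia,after,no,unknown,unskilled
78,eclampsia,after,no,unknown,unskilled
79,eclampsia,after,no,unknown,unskilled
80,eclampsia,after,no,unknown,unskilled
81,eclampsia,after,no,unknown,unskilled
82,eclampsia,after,no,unknown,unskilled
83,eclampsia,after,no,unknown,unskilled
84,eclampsia,after,no,unknown,unskilled
85,eclampsia,after,no,unknown,unknown
86,eclampsia,after,no,unknown,unknown
87,obstructed_labor,during,no,unknown,unskilled
88,obstructed_labor,during,no,unknown,unskilled
89,ruptured_uterus,before,yes,home,unskilled
90,ruptured_uterus,after,no,unknown,unskilled
91,other_direct,before,yes,home,skilled
92,other_direct,before,yes,home,skilled
93,other_direct,before,yes,home,skilled
94,other_direct,before,yes,home,skilled
95,other_direct,before,yes,home,skilled
96,other_direct,before,no,facility,skilled
97,other_direct,before,no,facility,unskilled
98,other_direct,during,no,facility,unskilled
99,other_direct,during,no,facility,unskilled
100,other_direct,after,no,facility,unskilled
101,other_direct,after,no,unknown,unskilled
102,other_direct,after,no,unknown,unskilled
103,other_direct,after,no,unknown,unskilled
104,other_direct,after,no,unknown,unskilled
105,other_direct,after,no,unknown,unskilled
106,other_direct,after,no,unknown,unskilled
107,other_direct,after,no,unknown,unskilled
108,other_direct,after,no,unknown,unskilled
109,other_direct,after,no,unknown,unskilled
110,other_direct,unknown,no,unknown,unskilled
111,indirect,before,no,home,skilled
112,indirect,before,no,home,unskilled
113,indirect,before,no,home,unskilled
114,indirect,after,no,facility,unskilled
115,indirect,after,no,unknown,unskilled
116,indirect,after,no,unknown,unskilled
117,indirect,after,no,unknown,unskilled
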