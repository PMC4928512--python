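code	name	cerebellar
1	Precentral_L	0
2	Precentral_R	0
3	Frontal_Sup_L	0
4	Frontal_Sup_R	0
5	Frontal_Sup_Orb_L	0
6	Frontal_Sup_Orb_R	0
7	Frontal_Mid_L	0
8	Frontal_Mid_R	0
9	Frontal_Mid_Orb_L	0
10	Frontal_Mid_Orb_R	0
11	Frontal_Inf_Oper_L	0
12	Frontal_Inf_Oper_R	0
13	Frontal_Inf_Tri_L	0
14	Frontal_Inf_Tri_R	0
15	Frontal_Inf_Orb_L	0
16	Frontal_Inf_Orb_R	0
17	Rolandic_Oper_L	0
18	Rolandic_Oper_R	0
19	Supp_Motor_Area_L	0
20	Supp_Motor_Area_R	0
21	Olfactory_L	0
22	Olfactory_R	0
23	Frontal_Sup_Medial_L	0
24	Frontal_Sup_Medial_R	0
25	Frontal_Med_Orb_L	0
26	Frontal_Med_Orb_R	0
27	Rectus_L	0
28	Rectus_R	0
29	Insula_L	0
30	Insula_R	0
31	Cingulum_Ant_L	0
32	Cingulum_Ant_R	0
33	Cingulum_Mid_L	0
34	Cingulum_Mid_R	0
35	Cingulum_Post_L	0
36	Cingulum_Post_R	0
37	Hippocampus_L	0
38	Hippocampus_R	0
39	ParaHippocampal_L	0
40	ParaHippocampal_R	0
41	Amygdala_L	0
42	Amygdala_R	0
43	Calcarine_L	0
44	Calcarine_R	0
45	Cuneus_L	0
46	Cuneus_R	0
47	Lingual_L	0
48	Lingual_R	0
49	Occipital_Sup_L	0
50	Occipital_Sup_R	0
51	Occipital_Mid_L	0
52	Occipital_Mid_R	0
53	Occipital_Inf_L	0
54	Occipital_Inf_R	0
55	Fusiform_L	0
56	Fusiform_R	0
57	Postcentral_L	0
58	Postcentral_R	0
59	Parietal_Sup_L	0
60	Parietal_Sup_R	0
61	Parietal_Inf_L	0
62	Parietal_Inf_R	0
63	SupraMarginal_L	0
64	SupraMarginal_R	0
65	Angular_L	0
66	Angular_R	0
67	Precuneus_L	0
68	Precuneus_R	0
69	Paracentral_Lobule_L	0
70	Paracentral_Lobule_R	0
71	Caudate_L	0
72	Caudate_R	0
73	Putamen_L	0
74	Putamen_R	0
75	Pallidum_L	0
76	Pallidum_R	0
77	Thalamus_L	0
78	Thalamus_R	0
79	Heschl_L	0
80	Heschl_R	0
81	Temporal_Sup_L	0
82	Temporal_Sup_R	0
83	Temporal_Pole_Sup_L	0
84	Temporal_Pole_Sup_R	0
85	Temporal_Mid_L	0
86	Temporal_Mid_R	0
87	Temporal_Pole_Mid_L	0
88	Temporal_Pole_Mid_R	0
89	Temporal_Inf_L	0
90	Temporal_Inf_R	0
91	Cerebelum_Crus1_L	1
92	Cerebelum_Crus1_R	1
93	Cerebelum_Crus2_L	1
94	Cerebelum_Crus2_R	1
95	Cerebelum_3_L	1
96	Cerebelum_3_R	1
97	Cerebelum_4_5_L	1
98	Cerebelum_4_5_R	1
99	Cerebelum_6_L	1
100	Cerebelum_6_R	1
101	Cerebelum_7b_L	1
102	Cerebelum_7b_R	1
103	Cerebelum_8_L	1
104	Cerebelum_8_R	1
105	Cerebelum_9_L	1
106	Cerebelum_9_R	1
107	Cerebelum_10_L	1
108	Cerebelum_10_R	1
109	Vermis_1_2	1
110	Vermis_3	1
111	Vermis_4_5	1
112	Vermis_6	1
113	Vermis_7	1
114	Vermis_8	1
115	Vermis_9	1
116	Vermis_10	1
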