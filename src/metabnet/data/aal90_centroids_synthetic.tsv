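code	name	x	y	z
1	Precentral_L	-45.4	-4.0	-10.0
2	Precentral_R	28.8	-80.5	-18.6
3	Frontal_Sup_L	-34.5	42.5	55.3
4	Frontal_Sup_R	10.5	-64.3	-15.0
5	Frontal_Sup_Orb_L	-30.7	-24.1	40.6
6	Frontal_Sup_Orb_R	54.6	1.9	7.4
7	Frontal_Mid_L	-44.5	44.9	14.9
8	Frontal_Mid_R	40.1	18.2	50.2
9	Frontal_Mid_Orb_L	-47.3	-67.5	54.3
10	Frontal_Mid_Orb_R	11.6	-45.7	0.4
11	Frontal_Inf_Oper_L	-28.8	52.4	23.1
12	Frontal_Inf_Oper_R	28.8	-10.2	-7.1
13	Frontal_Inf_Tri_L	-22.3	-77.9	23.7
14	Frontal_Inf_Tri_R	37.3	-78.7	42.4
15	Frontal_Inf_Orb_L	-27.5	-19.1	39.3
16	Frontal_Inf_Orb_R	25.5	-69.3	4.1
17	Rolandic_Oper_L	-52.8	-53.9	9.9
18	Rolandic_Oper_R	43.5	-16.6	0.1
19	Supp_Motor_Area_L	-30.0	-89.9	31.8
20	Supp_Motor_Area_R	32.1	52.8	-16.4
21	Olfactory_L	-30.8	-52.0	64.8
22	Olfactory_R	45.4	32.8	-9.9
23	Frontal_Sup_Medial_L	-31.2	32.7	11.0
24	Frontal_Sup_Medial_R	35.8	-82.4	52.8
25	Frontal_Med_Orb_L	-12.9	-2.6	-22.6
26	Frontal_Med_Orb_R	27.0	55.2	-1.7
27	Rectus_L	-24.7	-69.6	-24.7
28	Rectus_R	31.4	-80.9	34.6
29	Insula_L	-22.2	-51.2	35.9
30	Insula_R	46.5	59.9	-6.5
31	Cingulum_Ant_L	-23.0	-2.4	-20.4
32	Cingulum_Ant_R	18.6	33.9	26.4
33	Cingulum_Mid_L	-18.4	-33.2	52.4
34	Cingulum_Mid_R	45.4	-71.8	-9.2
35	Cingulum_Post_L	-32.6	40.1	-3.1
36	Cingulum_Post_R	49.7	21.4	46.0
37	Hippocampus_L	-34.8	22.0	-11.3
38	Hippocampus_R	35.2	-68.8	22.0
39	ParaHippocampal_L	-32.6	27.1	57.7
40	ParaHippocampal_R	26.8	9.9	43.1
41	Amygdala_L	-51.8	59.6	-29.6
42	Amygdala_R	28.0	37.2	30.3
43	Calcarine_L	-42.9	46.7	59.2
44	Calcarine_R	34.7	27.4	19.4
45	Cuneus_L	-9.3	-80.5	-5.9
46	Cuneus_R	53.5	38.1	17.2
47	Lingual_L	-23.0	23.6	31.2
48	Lingual_R	51.2	15.3	25.2
49	Occipital_Sup_L	-10.8	-69.9	-17.5
50	Occipital_Sup_R	36.8	-85.0	31.4
51	Occipital_Mid_L	-37.5	-14.1	-19.2
52	Occipital_Mid_R	17.5	-89.6	-16.0
53	Occipital_Inf_L	-51.4	23.9	6.1
54	Occipital_Inf_R	28.2	-46.8	-9.4
55	Fusiform_L	-11.0	-16.8	11.2
56	Fusiform_R	26.0	1.5	-3.4
57	Postcentral_L	-20.6	-39.9	40.5
58	Postcentral_R	18.0	-16.5	6.4
59	Parietal_Sup_L	-30.2	-73.5	-8.7
60	Parietal_Sup_R	30.9	-30.1	-10.5
61	Parietal_Inf_L	-53.2	48.3	8.7
62	Parietal_Inf_R	11.7	-59.4	44.9
63	SupraMarginal_L	-54.9	44.9	-10.7
64	SupraMarginal_R	33.9	-41.7	52.2
65	Angular_L	-15.1	-70.8	44.7
66	Angular_R	31.1	-84.3	21.4
67	Precuneus_L	-12.1	46.4	58.0
68	Precuneus_R	20.2	16.4	1.2
69	Paracentral_Lobule_L	-33.7	-11.0	38.8
70	Paracentral_Lobule_R	30.3	20.7	-10.6
71	Caudate_L	-35.2	48.1	-1.9
72	Caudate_R	25.8	-33.5	20.6
73	Putamen_L	-26.9	-33.1	50.8
74	Putamen_R	27.9	-76.9	-23.5
75	Pallidum_L	-24.5	-35.1	46.8
76	Pallidum_R	46.2	-23.7	22.3
77	Thalamus_L	-31.2	21.4	63.7
78	Thalamus_R	45.7	-56.5	54.7
79	Heschl_L	-26.0	24.6	-6.2
80	Heschl_R	38.1	55.9	24.8
81	Temporal_Sup_L	-26.5	-1.5	38.5
82	Temporal_Sup_R	19.6	-17.8	2.7
83	Temporal_Pole_Sup_L	-22.6	-43.7	29.4
84	Temporal_Pole_Sup_R	41.2	52.6	1.2
85	Temporal_Mid_L	-22.2	17.2	31.7
86	Temporal_Mid_R	11.0	-64.5	-4.0
87	Temporal_Pole_Mid_L	-24.2	13.0	-3.5
88	Temporal_Pole_Mid_R	18.6	39.8	-28.5
89	Temporal_Inf_L	-21.4	-35.2	41.8
90	Temporal_Inf_R	22.8	2.0	-3.6
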