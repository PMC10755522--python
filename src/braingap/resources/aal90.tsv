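region_id	region_name	lobe	hemisphere
1	Precentral_L	frontal	left
2	Precentral_R	frontal	right
3	Frontal_Sup_L	frontal	left
4	Frontal_Sup_R	frontal	right
5	Frontal_Sup_Orb_L	frontal	left
6	Frontal_Sup_Orb_R	frontal	right
7	Frontal_Mid_L	frontal	left
8	Frontal_Mid_R	frontal	right
9	Frontal_Mid_Orb_L	frontal	left
10	Frontal_Mid_Orb_R	frontal	right
11	Frontal_Inf_Oper_L	frontal	left
12	Frontal_Inf_Oper_R	frontal	right
13	Frontal_Inf_Tri_L	frontal	left
14	Frontal_Inf_Tri_R	frontal	right
15	Frontal_Inf_Orb_L	frontal	left
16	Frontal_Inf_Orb_R	frontal	right
17	Rolandic_Oper_L	frontal	left
18	Rolandic_Oper_R	frontal	right
19	Supp_Motor_Area_L	frontal	left
20	Supp_Motor_Area_R	frontal	right
21	Olfactory_L	limbic	left
22	Olfactory_R	limbic	right
23	Frontal_Sup_Medial_L	frontal	left
24	Frontal_Sup_Medial_R	frontal	right
25	Frontal_Med_Orb_L	frontal	left
26	Frontal_Med_Orb_R	frontal	right
27	Rectus_L	frontal	left
28	Rectus_R	frontal	right
29	Insula_L	limbic	left
30	Insula_R	limbic	right
31	Cingulum_Ant_L	limbic	left
32	Cingulum_Ant_R	limbic	right
33	Cingulum_Mid_L	limbic	left
34	Cingulum_Mid_R	limbic	right
35	Cingulum_Post_L	limbic	left
36	Cingulum_Post_R	limbic	right
37	Hippocampus_L	limbic	left
38	Hippocampus_R	limbic	right
39	ParaHippocampal_L	limbic	left
40	ParaHippocampal_R	limbic	right
41	Amygdala_L	limbic	left
42	Amygdala_R	limbic	right
43	Calcarine_L	occipital	left
44	Calcarine_R	occipital	right
45	Cuneus_L	occipital	left
46	Cuneus_R	occipital	right
47	Lingual_L	occipital	left
48	Lingual_R	occipital	right
49	Occipital_Sup_L	occipital	left
50	Occipital_Sup_R	occipital	right
51	Occipital_Mid_L	occipital	left
52	Occipital_Mid_R	occipital	right
53	Occipital_Inf_L	occipital	left
54	Occipital_Inf_R	occipital	right
55	Fusiform_L	occipital	left
56	Fusiform_R	occipital	right
57	Postcentral_L	parietal	left
58	Postcentral_R	parietal	right
59	Parietal_Sup_L	parietal	left
60	Parietal_Sup_R	parietal	right
61	Parietal_Inf_L	parietal	left
62	Parietal_Inf_R	parietal	right
63	SupraMarginal_L	parietal	left
64	SupraMarginal_R	parietal	right
65	Angular_L	parietal	left
66	Angular_R	parietal	right
67	Precuneus_L	parietal	left
68	Precuneus_R	parietal	right
69	Paracentral_Lobule_L	frontal	left
70	Paracentral_Lobule_R	frontal	right
71	Caudate_L	subcortical	left
72	Caudate_R	subcortical	right
73	Putamen_L	subcortical	left
74	Putamen_R	subcortical	right
75	Pallidum_L	subcortical	left
76	Pallidum_R	subcortical	right
77	Thalamus_L	subcortical	left
78	Thalamus_R	subcortical	right
79	Heschl_L	temporal	left
80	Heschl_R	temporal	right
81	Temporal_Sup_L	temporal	left
82	Temporal_Sup_R	temporal	right
83	Temporal_Pole_Sup_L	temporal	left
84	Temporal_Pole_Sup_R	temporal	right
85	Temporal_Mid_L	temporal	left
86	Temporal_Mid_R	temporal	right
87	Temporal_Pole_Mid_L	temporal	left
88	Temporal_Pole_Mid_R	temporal	right
89	Temporal_Inf_L	temporal	left
90	Temporal_Inf_R	temporal	right
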