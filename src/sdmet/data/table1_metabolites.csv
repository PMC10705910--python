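index,rt,name
,,Organic acids
1,9:37,Thioglycolic acid
2,10:23,Fumaric acid
3,10:24,Lactic acid
4,10:32,Acetic acid
5,10:39,Mercaptoacetic acid
6,11:34,Acetimidic acid
7,11:52,Allylacetic acid
8,12:28,Propanedioc acid
9,13:09,DL-malic (butanedioic) acid
10,13:19,Gluconic acid
11,14:26,Itaconic acid
12,14:30,Propanoic acid
13,14:58,Erythronic acid
14,14:59,Malonic acid
15,15:03,Succinic acid
16,15:09,Pentonic acid
17,16:33,Malic acid
18,16:56,Aspartic acid
19,16:59,Isocitric asid lactone
20,17:09,Monoamidoethylmalonic acid
21,17:51,Pentanoic acid
22,17:59,Erythro-pentonic acid
23,16:31,Succinic anhydride
24,18:06,Glutamic acid
25,18:12,Monoamidoethylmalonic acid
26,20:13,Schikimic acid
27,20:26,Citric acid
28,21:06,Quinic acid
29,21:18,Altronic acid
30,21:49,Acrylic acid
31,23:23,Coffeic acid
32,28:43,Galactaric acid
,,Phenolic compounds
33,19:37,Benzoic acid
34,19:48,Cinnamic acid
35,21:05,Quinic acid
36,22:53,Ferulic acid
37,40:50,Chlorogenic acid
,,Fatty acids
38,21:15,Hexadecanoic acid
,,Carbohydrates (CBs)
39,17:02,Erythritol
40,18:19,Xylonic acid
41,18:36,D-(−)-Ribofuranose
42,19:22,D-Xylopyranose
43,19:26,D-Galactose
44,19:43,"Gluconic acid, γ-lacton"
45,19:43,L-(−)-Arabitol
46,19:43,Ribitol
47,20:11,D-(−)Tagatofuranose
48,20:36,D-(−)-Fructofuranose
49,20:51,D-(−)-Fructopyranose
50,20:51,1.5-Anhydroglucitol
51,20:53,Levoglucosan
52,21:01,Psicopyranose
53,21:13,Methylgalactoside
54,21:22,β-DL-arabinopyranose
55,21:17,Glyceryl-glycoside
56,21:31,Lactulose
57,21:32,Allopyranose
58,21:51,Inositol
59,22:03,Sorbitol
60,22:15,Allofuranose
61,22:17,β-D-Glucopyranose
62,22:26,Fructose
63,22:28,Talofuranose
64,23:13,D-Galacturonic acid
65,24:03,Hexopyranose
66,24:15,Lactose
67,30:03,Lactose
68,30:48,D-(+)-Turanose
69,31:02,Furanose
70,34:25,Dioxyfructose
71,35:55,Maltose
72,37:08,D-(+)-Cellobiose
,,Aminosugars
73,19:22,N-acetil-glucosamin
,,Amino acids and their derivatives
74,12:06,L-Leucine
75,12.53,L-Norvaline
76,14:48,Uracil-5-carboxylate decarboxylase
77,15:08,6-Azauracil
78,15:23,L-Treonin
79,16:48,L-Proline
80,17:20,Citrullin
,,Other connections
81,12:51,Urea
82,13:43,Glycerol
83,13:50,Clycerol
84,16:00,2-Piperidone
85,17:41,Pirimidine
86,21:40,Octadecanamide
87,23:31,Myo-inositol
88,26:70,Glycerylglicoside
89,31:29,Aukubin
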