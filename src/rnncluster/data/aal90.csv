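index,abbrev,name
1,PreCG.L,"Precentral gyrus (L)"
2,PreCG.R,"Precentral gyrus (R)"
3,SFGdor.L,"Superior frontal gyrus, dorsolateral (L)"
4,SFGdor.R,"Superior frontal gyrus, dorsolateral (R)"
5,ORBsup.L,"Superior frontal gyrus, orbital part (L)"
6,ORBsup.R,"Superior frontal gyrus, orbital part (R)"
7,MFG.L,"Middle frontal gyrus (L)"
8,MFG.R,"Middle frontal gyrus (R)"
9,ORBmid.L,"Middle frontal gyrus, orbital part (L)"
10,ORBmid.R,"Middle frontal gyrus, orbital part (R)"
11,IFGoperc.L,"Inferior frontal gyrus, opercular part (L)"
12,IFGoperc.R,"Inferior frontal gyrus, opercular part (R)"
13,IFGtriang.L,"Inferior frontal gyrus, triangular part (L)"
14,IFGtriang.R,"Inferior frontal gyrus, triangular part (R)"
15,ORBinf.L,"Inferior frontal gyrus, orbital part (L)"
16,ORBinf.R,"Inferior frontal gyrus, orbital part (R)"
17,ROL.L,"Rolandic operculum (L)"
18,ROL.R,"Rolandic operculum (R)"
19,SMA.L,"Supplementary motor area (L)"
20,SMA.R,"Supplementary motor area (R)"
21,OLF.L,"Olfactory cortex (L)"
22,OLF.R,"Olfactory cortex (R)"
23,SFGmed.L,"Superior frontal gyrus, medial (L)"
24,SFGmed.R,"Superior frontal gyrus, medial (R)"
25,ORBsupmed.L,"Superior frontal gyrus, medial orbital (L)"
26,ORBsupmed.R,"Superior frontal gyrus, medial orbital (R)"
27,REC.L,"Gyrus rectus (L)"
28,REC.R,"Gyrus rectus (R)"
29,INS.L,"Insula (L)"
30,INS.R,"Insula (R)"
31,ACG.L,"Anterior cingulate and paracingulate gyri (L)"
32,ACG.R,"Anterior cingulate and paracingulate gyri (R)"
33,DCG.L,"Median cingulate and paracingulate gyri (L)"
34,DCG.R,"Median cingulate and paracingulate gyri (R)"
35,PCG.L,"Posterior cingulate gyrus (L)"
36,PCG.R,"Posterior cingulate gyrus (R)"
37,HIP.L,"Hippocampus (L)"
38,HIP.R,"Hippocampus (R)"
39,PHG.L,"Parahippocampal gyrus (L)"
40,PHG.R,"Parahippocampal gyrus (R)"
41,AMYG.L,"Amygdala (L)"
42,AMYG.R,"Amygdala (R)"
43,CAL.L,"Calcarine fissure and surrounding cortex (L)"
44,CAL.R,"Calcarine fissure and surrounding cortex (R)"
45,CUN.L,"Cuneus (L)"
46,CUN.R,"Cuneus (R)"
47,LING.L,"Lingual gyrus (L)"
48,LING.R,"Lingual gyrus (R)"
49,SOG.L,"Superior occipital gyrus (L)"
50,SOG.R,"Superior occipital gyrus (R)"
51,MOG.L,"Middle occipital gyrus (L)"
52,MOG.R,"Middle occipital gyrus (R)"
53,IOG.L,"Inferior occipital gyrus (L)"
54,IOG.R,"Inferior occipital gyrus (R)"
55,FFG.L,"Fusiform gyrus (L)"
56,FFG.R,"Fusiform gyrus (R)"
57,PoCG.L,"Postcentral gyrus (L)"
58,PoCG.R,"Postcentral gyrus (R)"
59,SPG.L,"Superior parietal gyrus (L)"
60,SPG.R,"Superior parietal gyrus (R)"
61,IPL.L,"Inferior parietal gyrus (L)"
62,IPL.R,"Inferior parietal gyrus (R)"
63,SMG.L,"Supramarginal gyrus (L)"
64,SMG.R,"Supramarginal gyrus (R)"
65,ANG.L,"Angular gyrus (L)"
66,ANG.R,"Angular gyrus (R)"
67,PCUN.L,"Precuneus (L)"
68,PCUN.R,"Precuneus (R)"
69,PCL.L,"Paracentral lobule (L)"
70,PCL.R,"Paracentral lobule (R)"
71,CAU.L,"Caudate nucleus (L)"
72,CAU.R,"Caudate nucleus (R)"
73,PUT.L,"Lenticular nucleus, putamen (L)"
74,PUT.R,"Lenticular nucleus, putamen (R)"
75,PAL.L,"Lenticular nucleus, pallidum (L)"
76,PAL.R,"Lenticular nucleus, pallidum (R)"
77,THA.L,"Thalamus (L)"
78,THA.R,"Thalamus (R)"
79,HES.L,"Heschl gyrus (L)"
80,HES.R,"Heschl gyrus (R)"
81,STG.L,"Superior temporal gyrus (L)"
82,STG.R,"Superior temporal gyrus (R)"
83,TPOsup.L,"Temporal pole: superior temporal gyrus (L)"
84,TPOsup.R,"Temporal pole: superior temporal gyrus (R)"
85,MTG.L,"Middle temporal gyrus (L)"
86,MTG.R,"Middle temporal gyrus (R)"
87,TPOmid.L,"Temporal pole: middle temporal gyrus (L)"
88,TPOmid.R,"Temporal pole: middle temporal gyrus (R)"
89,ITG.L,"Inferior temporal gyrus (L)"
90,ITG.R,"Inferior temporal gyrus (R)"
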