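region_id,name,hemisphere,network,x,y,z
1,pSTS_L,L,visual_sensory,-54,-40,2
2,pSTS_R,R,visual_sensory,54,-38,2
3,FG_L,L,visual_sensory,-42,-52,-18
4,FG_R,R,visual_sensory,42,-50,-18
5,MT-V5_L,L,visual_sensory,-46,-68,4
6,MT-V5_R,R,visual_sensory,48,-66,4
7,AM_L,L,limbic,-22,-4,-18
8,AM_R,R,limbic,24,-4,-18
9,HC_L,L,limbic,-28,-24,-12
10,HC_R,R,limbic,28,-24,-12
11,NAC_L,L,limbic,-10,10,-8
12,NAC_R,R,limbic,12,10,-8
13,vmPFC,midline,limbic,0,46,-14
14,rACC,midline,limbic,0,36,10
15,AI_L,L,intermediate,-34,20,-4
16,AI_R,R,intermediate,36,20,-4
17,aMCC,midline,intermediate,0,22,32
18,IFG_L,L,intermediate,-48,24,12
19,IFG_R,R,intermediate,50,24,12
20,SMA_L,L,intermediate,-8,0,58
21,SMA_R,R,intermediate,10,4,62
22,SMG_L,L,intermediate,-58,-40,34
23,SMG_R,R,intermediate,60,-40,34
24,Cereb_L,L,intermediate,-24,-76,-34
25,Cereb_R,R,intermediate,26,-74,-34
26,TP_L,L,higher_associative,-40,14,-32
27,TP_R,R,higher_associative,42,14,-32
28,MTG_L,L,higher_associative,-58,-16,-12
29,MTG_R,R,higher_associative,60,-14,-12
30,TPJ_L,L,higher_associative,-50,-58,26
31,TPJ_R,R,higher_associative,52,-56,26
32,dmPFC,midline,higher_associative,0,54,28
33,pMCC,midline,higher_associative,0,-18,40
34,FP,midline,higher_associative,0,62,2
35,PCC,midline,higher_associative,0,-52,26
36,Prec,midline,higher_associative,0,-64,42
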