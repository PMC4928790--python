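patient_no,age,diagnosis,lesions,aetiology,aetiology_raw,delay_first_crsr,n_crsr,delay_last_crsr,rehab_duration,outcome,return_home,walk
1,20,UWS,"bF, rT, rP, rBG",TBI,TBI,19,4,54,21,Non DOC,Yes,Yes
2,76,UWS,"rP, rO",IS,IS,15,4,70,59,Non DOC,No,No
3,51,MCS,"lF, bT, bP",TBI,TBI,5,3,41,16,MCS,No,Yes
4,57,UWS,"rF, rT",HS (RA),HS (RA),27,4,61,21,MCS,Yes,Yes
5,48,MCS,Pons,HS,HS,9,3,94,55,Non DOC,No,No
6,25,MCS,"rF, bT, rP",TBI,TBI,13,3,94,7,Non DOC,Yes,Yes
7,53,MCS,"bT, lP",TBI,TBI,9,4,25,19,Non DOC,Yes,Yes
8,67,UWS,"lF, lP, rO",IS (RA),IS (RA),18,4,41,48,Non DOC,Yes,Yes
9,53,MCS,rBG,Inf,Inf,12,6,98,21,Non DOC,Yes,Yes
10,41,UWS,"rF, rT, rP, rBG",HS,HS,5,7,34,20,Non DOC,No,No
11,24,UWS,"bF, lBG, DAI",TBI,TBI,9,7,52,35,MCS,Yes,No
12,65,MCS,lBG,Inf,Inf,12,6,60,33,MCS,NA,NA
13,68,MCS,"lF, lP",HS,HS,6,3,39,37,Non DOC,No,No
14,65,MCS,bF,"TBI, IS","TBI, IS",7,3,26,14,Non DOC,Yes,Yes
15,18,UWS,"bF, bT, lBG, Mes",TBI,TBI,15,6,69,41,MCS,Yes,Yes
16,55,UWS,"rT, rP",HS,HS,14,3,54,20,Non DOC,Yes,Yes
17,24,MCS,rT,TBI,TBI,4,3,26,8,Non DOC,Yes,Yes
18,73,UWS,Pons,"IS, IVH","IS, IVH",7,9,56,43,Non DOC,Yes,NA
19,68,UWS,bF,TBI,TBI,2,3,24,15,Non DOC,Yes,Yes
20,37,UWS,"bF, bT, bP, bO, bBG",Anoxia,Anoxia,8,8,65,24,UWS,No,No
21,35,UWS,"bF, bT, lP",TBI,TBI,18,7,59,33,UWS,No,No
22,49,UWS,"bBG, Mes, Pons",IS,IS,27,6,65,42,MCS,No,No
23,20,MCS,"bF, bT, bP, DAI",TBI,TBI,7,3,33,13,Non DOC,Yes,Yes
24,66,MCS,bT,TBI,TBI,9,3,25,13,Non DOC,Yes,Yes
25,24,UWS,"bBG, Mes, Pons",TBI (Op),TBI (PO,5,9,48,36,MCS,No,No
26,59,UWS,bF,TBI,TBI,11,3,31,14,Non DOC,Yes,Yes
27,22,UWS,"lF, lT, lP",TBI,TBI,11,8,31,8,UWS,No,No
28,53,UWS,"rF, rT",HS (RA),HS (RA),8,9,64,41,UWS,No,No
29,63,UWS,"bF, bP",IS (RA),IS (RA),18,10,71,48,Non DOC,Yes,Yes
30,62,UWS,"rF, rT, bP, bO",TBI (Op),TBI (Op),5,9,75,33,Non DOC,Yes,No
31,55,MCS,"bF, bP, bBG",HS,HS,1,7,53,36,Non DOC,Yes,Yes
32,42,UWS,"lBG, DAI",TBI,TBI,16,5,40,22,Non DOC,Yes,Yes
33,43,MCS,"lF, bBG, Mes",IS,IS,17,3,44,19,MCS,NA,NA
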