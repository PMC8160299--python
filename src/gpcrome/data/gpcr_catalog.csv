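# Curated GPCR / GPCR-signaling gene catalog (IUPHAR-style GRAFS families,
# human + mouse). Snapshot covers the microglial core signature, every gene
# discussed in the accompanying analyses, the downstream signaling mediators,
# and a small padding set so that all GRAFS families are represented.
# Completeness relative to the full non-sensory GPCRome is not claimed.
# version_tag: curated-2026-09
species,symbol,aliases,family,category,protein_name,ortholog
human,CX3CR1,GPR13;CMKBRL1,rhodopsin,gpcr,fractalkine receptor,
human,GPR34,,rhodopsin,gpcr,lysoPS receptor GPR34,
human,GPR183,EBI2,rhodopsin,gpcr,EBI2,
human,P2RY12,P2Y12,rhodopsin,gpcr,P2Y12,
human,P2RY13,GPR86,rhodopsin,gpcr,P2Y13,
human,P2RY6,,rhodopsin,gpcr,P2Y6,
human,ADGRG1,GPR56,adhesion,gpcr,GPR56,
human,ADORA3,A3AR,rhodopsin,gpcr,adenosine A3 receptor,
human,ADRB2,,rhodopsin,gpcr,beta-2 adrenoceptor,
human,CCR1,CMKBR1,rhodopsin,gpcr,CCR1,
human,C3AR1,,rhodopsin,gpcr,C3a receptor,
human,C5AR1,CD88,rhodopsin,gpcr,C5a receptor 1,
human,C5AR2,GPR77,rhodopsin,gpcr,C5a receptor 2,
human,LPAR5,GPR92,rhodopsin,gpcr,LPA5,
human,LPAR6,P2RY5,rhodopsin,gpcr,LPA6,
human,PTAFR,,rhodopsin,gpcr,PAF receptor,
human,CXCR4,,rhodopsin,gpcr,CXCR4,
human,PTGER4,EP4,rhodopsin,gpcr,EP4 receptor,
human,ADGRE1,EMR1,adhesion,gpcr,EMR1,
human,ADGRE5,CD97,adhesion,gpcr,CD97,
human,ADGRB1,BAI1,adhesion,gpcr,BAI1,
human,CCR6,,rhodopsin,gpcr,CCR6,
human,GPR84,,rhodopsin,gpcr,GPR84,
human,GPR146,,rhodopsin,gpcr,GPR146,
human,FPR1,,rhodopsin,gpcr,formyl peptide receptor 1,
human,ACKR3,CXCR7,rhodopsin,gpcr,atypical chemokine receptor 3,
human,MRGPRX2,,rhodopsin,gpcr,MRGPRX2,Mrgprb2
human,P2RY8,,rhodopsin,gpcr,P2Y8,
human,GRM3,,glutamate,gpcr,mGlu3,
human,GRM5,,glutamate,gpcr,mGlu5,
human,VIPR1,VPAC1,secretin,gpcr,VPAC1,
human,SCTR,,secretin,gpcr,secretin receptor,
human,FZD7,,frizzled,gpcr,frizzled-7,
human,SMO,,frizzled,gpcr,smoothened,
human,GNAI2,,none,g_protein,G-alpha-i2,
human,GNAS,,none,g_protein,G-alpha-s,
human,GNA12,,none,g_protein,G-alpha-12,
human,GNA13,,none,g_protein,G-alpha-13,
human,GNA15,,none,g_protein,G-alpha-15,
human,GRK2,ADRBK1,none,grk,GRK2,
human,ARRB2,,none,arrestin,beta-arrestin 2,
mouse,Cx3cr1,,rhodopsin,gpcr,fractalkine receptor,
mouse,Gpr34,,rhodopsin,gpcr,lysoPS receptor GPR34,
mouse,Gpr183,Ebi2,rhodopsin,gpcr,EBI2,
mouse,P2ry12,,rhodopsin,gpcr,P2Y12,
mouse,P2ry13,,rhodopsin,gpcr,P2Y13,
mouse,P2ry6,,rhodopsin,gpcr,P2Y6,
mouse,Adgrg1,Gpr56,adhesion,gpcr,GPR56,
mouse,Adora3,,rhodopsin,gpcr,adenosine A3 receptor,
mouse,Adrb2,,rhodopsin,gpcr,beta-2 adrenoceptor,
mouse,Ccr1,,rhodopsin,gpcr,CCR1,
mouse,C3ar1,,rhodopsin,gpcr,C3a receptor,
mouse,C5ar1,,rhodopsin,gpcr,C5a receptor 1,
mouse,C5ar2,,rhodopsin,gpcr,C5a receptor 2,
mouse,Lpar5,,rhodopsin,gpcr,LPA5,
mouse,Lpar6,,rhodopsin,gpcr,LPA6,
mouse,Ptafr,,rhodopsin,gpcr,PAF receptor,
mouse,Cxcr4,,rhodopsin,gpcr,CXCR4,
mouse,Ptger4,,rhodopsin,gpcr,EP4 receptor,
mouse,Adgre1,Emr1,adhesion,gpcr,F4/80,
mouse,Adgre5,Cd97,adhesion,gpcr,CD97,
mouse,Adgrb1,Bai1,adhesion,gpcr,BAI1,
mouse,Ccr6,,rhodopsin,gpcr,CCR6,
mouse,Gpr84,,rhodopsin,gpcr,GPR84,
mouse,Gpr146,,rhodopsin,gpcr,GPR146,
mouse,Fpr1,,rhodopsin,gpcr,formyl peptide receptor 1,
mouse,Ackr3,Cxcr7,rhodopsin,gpcr,atypical chemokine receptor 3,
mouse,Mrgprb2,,rhodopsin,gpcr,MRGPRB2,MRGPRX2
mouse,Grm3,,glutamate,gpcr,mGlu3,
mouse,Grm5,,glutamate,gpcr,mGlu5,
mouse,Vipr1,,secretin,gpcr,VPAC1,
mouse,Sctr,,secretin,gpcr,secretin receptor,
mouse,Fzd7,,frizzled,gpcr,frizzled-7,
mouse,Smo,,frizzled,gpcr,smoothened,
mouse,Gnai2,,none,g_protein,G-alpha-i2,
mouse,Gnas,,none,g_protein,G-alpha-s,
mouse,Gna12,,none,g_protein,G-alpha-12,
mouse,Gna13,,none,g_protein,G-alpha-13,
mouse,Gna15,,none,g_protein,G-alpha-15,
mouse,Grk2,Adrbk1,none,grk,GRK2,
mouse,Arrb2,,none,arrestin,beta-arrestin 2,
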