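part_id,addgene_id,category,description,fusion_5,fusion_3,resistance,sequence
pEPQD0KN0024,162281,acceptor_ecoli_cfps,"T7 promoter, RBS, N-term exp. tag, T7 terminator, kanR, pUC ori",AATG,GCTT,kanR,
pEPQD0KN0244,162282,acceptor_ecoli_cfps,"T7 promoter, RBS, N-term exp. tag, T7 terminator, kanR, pUC ori",CCAT,GCTT,kanR,
pEPQD0KN0025,162283,acceptor_ecoli_cfps,"T7 promoter, RBS, T7 terminator, kanR, pUC ori",AATG,GCTT,kanR,
pEPQD0KN0245,162284,acceptor_ecoli_cfps,"T7 promoter, RBS, T7 terminator, kanR, pUC ori",CCAT,GCTT,kanR,
pEPQD0CB0026,162285,acceptor_wheatgerm,"SP6 promoter, EO1 enhancer, folA terminator, ampR, pUC ori",AATG,GCTT,ampR,
pEPQD0CB0246,162286,acceptor_wheatgerm,"SP6 promoter, EO1 enhancer, folA terminator, ampR, pUC ori",CCAT,GCTT,ampR,
pEPQD0KN0282,162287,acceptor_wheatgerm,"SP6 promoter, EO1 enhancer, T7 terminator, kanR, pUC ori",AATG,GCTT,kanR,
pEPQD0KN0283,162288,acceptor_wheatgerm,"SP6 promoter, EO1 enhancer, T7 terminator, kanR, pUC ori",CCAT,GCTT,kanR,
pEPQD0KN0284,162289,acceptor_wheatgerm,"SP6 promoter, EO1 enhancer, folA terminator, kanR, pUC ori",AATG,GCTT,kanR,
pEPQD0KN0285,162290,acceptor_wheatgerm,"SP6 promoter, EO1 enhancer, folA terminator, kanR, pUC ori",CCAT,GCTT,kanR,
pEPMY1CB0001,162317,acceptor_ecoli_cell,"T7 promoter, lac operator, RBS, T7 terminator, ampR, pUC ori",CCAT,GCTT,ampR,
pEPYC0CM0258,162291,n_tag,HiBiT,CCAT,AATG,,
pEPQD0CM0541,162292,n_tag,GST-[thrombin cleavage site],CCAT,AATG,,
pEPQD0CM0542,162293,n_tag,HiBiT-GST-[thrombin cleavage site],CCAT,AATG,,
pEPQD0CM0543,162294,n_tag,GST-[TEV cleavage site],CCAT,AATG,,
pEPQD0CM0544,162295,n_tag,MBP-[Factor Xa cleavage site],CCAT,AATG,,
pEPQD0CM0545,162296,n_tag,HiBiT-MBP-[Factor Xa cleavage site],CCAT,AATG,,
pEPQD0CM0546,162297,n_tag,MBP-[TEV cleavage site],CCAT,AATG,,
pEPQD0CM0547,162298,n_tag,TrxA-[TEV cleavage site],CCAT,AATG,,
pEPQD0CM0548,162299,n_tag,HiBiT-TrxA-[TEV cleavage site],CCAT,AATG,,
pEPQD0CM0549,162300,n_tag,SUMO-[TEV cleavage site],CCAT,AATG,,
pEPQD0CM0550,162301,n_tag,HiBiT-SUMO-[TEV cleavage site],CCAT,AATG,,
pEPQD0CM0281,162302,n_tag,[S-tag]-[TEV cleavage site],CCAT,AATG,,
pEPQD0CM0551,162303,n_tag,HiBiT-[S-tag]-[TEV cleavage site],CCAT,AATG,,
pEPMY0SP0002,162304,n_tag,6xHis tag-[HRV 3C cleavage site],CCAT,AATG,,
pEPQD0CM0296,162305,cds,"superfolder GFP, no stop codon",AATG,TTCG,,
pEPQD0CM0539,162306,cds,"TEV protease (S219V), no stop codon",AATG,TTCG,,
pEPYC0CM0134,162307,c_tag,"HiBiT-stop, frame1 (NNT-TCG)",TTCG,GCTT,,
pEPYC0CM0257,162308,c_tag,"HiBiT-stop, frame2 (TTC-G)",TTCG,GCTT,,
pEPQD0CM0027,162309,c_tag,"9-amino acid linker, superfolder GFP, strep tag, stop codon",TTCG,GCTT,,
pEPQD0CM0028,162310,c_tag,"9-amino acid linker, strep tag, stop codon",TTCG,GCTT,,
pEPQD0CM0029,162311,c_tag,"strep tag, stop codon",TTCG,GCTT,,
pEPQD0CM0030,162312,c_tag,stop codon,TTCG,GCTT,,
pEPQDKN0248,162313,reporter,T7prom-RBS-sfGFP-HiBiT,n/a,n/a,,
pEPQDKN0332,162314,reporter,SP6prom-EO1-sfGFP-HiBiT,n/a,n/a,,
pEPQDKN0329,162315,protease_reaction,T7prom-RBS-NET-TEVprotease-HiBiT,n/a,n/a,,
pEPQDKN0729,162316,protease_reaction,T7prom-RBS-NET-TEVprotease,n/a,n/a,,
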