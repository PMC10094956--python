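endpoint,hapten,real,predicted
eAR,Ammylcinnamyl alcohol,0,1
eAR,Citral,0,1
eAR,Geraniol,1,0
eAR,"Hydroxyisohexyl 3-cyclohexene carboxaldehyde (HICC, Lyral)",0,1
eAR,Neomycin,1,0
eAR,p-Phenylenediamine,1,0
eAR,Thimerosal,1,0
eOR,Benzocaine,0,1
eOR,Benzyl salicylate,0,1
eOR,Bronopol,1,0
eOR,Diazolidynyl urea,1,0
eOR,DMDM Hydantoin,1,0
eOR,Hydroxycitronellal,1,0
eOR,Isopropyl myristate,1,0
eOR,Methylchloroisothiazolinone,1,0
eOR,Myroxylon pereirae resin,1,0
eOR,Sorbitol,0,1
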