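substance,label_ear,label_eor,organic
Ammylcinnamyl alcohol,0,1,true
Benzocaine,0,0,true
Benzyl alcohol,0,1,true
Benzyl salicylate,0,0,true
Black rubber mix,0,1,true
Butylhydroxyanisole (BHA),1,1,true
Bronopol,1,1,true
Cinnamal,1,1,true
Cinnamic alcohol,1,1,true
Citral,0,1,true
Cocamidopropyl betaine,1,0,true
Colophonium,1,1,true
Diazolidynyl urea,1,1,true
DMDM Hydantoin,1,1,true
Epoxy resin,0,0,true
Evernia prunastri extract,0,0,true
Farnesol,0,0,true
Formaldehyde,1,1,true
Geraniol,1,1,true
Hydroxycitronellal,1,1,true
Imidazolidynyl urea,0,0,true
Iodopropynyl butylcarbamate,0,0,true
Isopropyl myristate,0,1,true
Lanolin,0,0,true
"Hydroxyisohexyl 3-cyclohexene carboxaldehyde (HICC, Lyral)",0,0,true
Mercapto mix,0,0,true
Mercaptobenzothiazole,0,1,true
Methylchloroisothiazolinone (MCI),1,1,true
Methyldibromo Glutaronitrile (MDBGN),1,0,true
Methylisothiazolinone (MI),1,0,true
Myroxylon pereirae resin,1,1,true
Neomycin sulfate,1,1,true
Paraben mix,0,1,true
p-Phenylenediamine (PPD),1,1,true
Propyl gallate,0,1,true
Quaternium 15,1,1,true
Quinoline mix,0,0,true
Sorbitan sesquilate,0,0,true
Thimerosal,1,1,true
Triethanolamine,0,1,true
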