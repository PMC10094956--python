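substance,me_acd,me_gen,ear,label,utilization
Benzocaine,0.50,1.00,-0.50,0,included
Sorbitan sesquioleate,0.60,0.50,0.10,0,included
Ammylcinnamyl alcohol,0.30,0.10,0.20,0,included
Isopropyl myristate,0.20,0.00,0.20,0,included
Benzyl salicylate,0.75,0.50,0.25,0,included
Iodopropynyl butylcarbamate,0.85,0.30,0.25,0,included
Benzyl alcohol,0.30,0.00,0.30,0,included
"Hydroxyisohexyl 3-cyclohexene carboxaldehyde (HICC, Lyral)",2.35,2.00,0.35,0,included
Citral,0.60,0.20,0.40,0,included
Mercaptobenzothiazole,0.60,0.20,0.40,0,included
Mercapto mix,0.80,0.30,0.50,0,included
Farnesol,1.05,0.40,0.65,0,included
Black rubber mix,0.85,0.20,0.65,0,included
Epoxy resin,1.25,0.60,0.65,0,included
Paraben mix,1.00,0.30,0.70,0,included
Propyl gallate,0.70,0.00,0.70,0,included
Quinoline mix,1.10,0.40,0.70,0,included
Evernia prunastri extract,1.55,0.75,0.75,0,included
Lanolin,1.70,0.95,0.75,0,included
Imidazolidynyl urea,1.30,0.50,0.80,0,included
Triethanolamine,0.80,0.00,0.80,0,included
Diazolidynyl urea,1.50,0.50,1.00,1,included
Bronopol,1.20,0.00,1.20,1,included
Cocamidopropyl betaine,3.20,2.00,1.20,1,included
Methyldibromo Glutaronitrile (MDBGN),2.80,1.60,1.20,1,included
Caine mix,1.30,0.10,1.20,1,excluded
DMDM Hydantoin,1.35,0.00,1.35,1,included
Butylhydroxyanisole (BHA),1.40,0.00,1.40,1,included
Quaternium 15,1.85,0.40,1.45,1,included
Formaldehyde,2.60,0.80,1.80,1,included
Cobalt (di)chloride,4.90,2.80,2.10,1,excluded
Ethylenediamine (dichloride),2.40,0.25,2.15,1,excluded
Colophonium,3.40,1.20,2.20,1,included
Wool alcohols,2.40,0.20,2.20,1,excluded
Thiuram mix,2.70,0.50,2.20,1,excluded
Methylchloroisothiazolinone/Methylisothiazolinone (MCI/MI),2.80,0.50,2.30,1,excluded
Methylisothiazolinone (MI),3.90,1.45,2.45,1,included
Hydroxycitronellal,4.05,0.50,3.55,1,included
Methylchloroisothiazolinone (MCI),4.00,0.20,3.80,1,included
p-Phenylenediamine (PPD),4.80,1.00,3.80,1,included
Geraniol,4.25,0.40,3.85,1,included
Fragrance Mix II (FM II),4.90,0.90,4.00,1,excluded
Carba mix,4.60,0.50,4.10,1,excluded
Cinnamal,5.15,0.80,4.35,1,included
Potassium dichromate,5.40,0.80,4.60,1,excluded
Neomycin sulfate,5.05,0.40,4.65,1,included
Myroxylon pereirae resin,6.50,1.10,5.40,1,included
Thimerosal,10.20,3.40,6.80,1,included
Fragrance Mix I (FM I),9.40,2.45,6.95,1,excluded
Cinnamic alcohol,8.30,0.30,8.00,1,included
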