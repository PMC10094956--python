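substance,me_acd,me_gen,eor,label,utilization
Benzocaine,0.50,1.00,0.50,0,included
Hydroxyisohexyl 3-cyclohexene carboxaldehyde (HICC)-Lyral,2.35,2.00,1.17,0,included
Sorbitan sesquioleate,0.60,0.50,1.20,0,included
Iodopropynyl butylcarbamate,0.85,0.60,1.42,0,included
Benzyl salicylate,0.75,0.50,1.50,0,included
Cocamidopropyl betaine,3.20,2.00,1.60,0,included
Cobalt (di)chloride,4.90,2.80,1.75,0,excluded
Methyldibromo Glutaronitrile (MDBGN),2.80,1.60,1.75,0,included
Lanolin,1.70,0.95,1.79,0,included
Evernia prunastri extract,1.55,0.75,2.06,0,included
Epoxy resin,1.25,0.60,2.08,0,included
Imidazolidynyl urea,1.30,0.50,2.60,0,included
Farnesol,1.05,0.40,2.62,0,included
Mercapto mix,0.80,0.30,2.67,0,included
Methylisothiazolinone (MI),3.90,1.45,2.69,0,included
Quinoline mix,1.10,0.40,2.75,0,included
Diazolidynyl urea,1.50,0.50,3.00,1,included
Ammylcinnamyl alcohol,0.30,0.10,3.00,1,included
Mercaptobenzothiazole,0.60,0.20,3.00,1,included
Thimerosal,10.20,3.40,3.00,1,included
Formaldehyde,2.60,0.80,3.25,1,included
Paraben mix,1.00,0.30,3.33,1,excluded
Colophonium,3.90,1.10,3.55,1,included
Fragrance Mix I (FM I),9.40,2.45,3.87,1,excluded
Black rubber mix,0.85,0.20,4.25,1,excluded
Quaternium 15,1.85,0.40,4.63,1,included
p-Phenylenediamine (PPD),4.80,1.00,4.80,1,included
Thiuram mix,2.70,0.50,5.40,1,excluded
Fragrance Mix II (FM II),4.90,0.90,5.44,1,excluded
Methylchloroisothiazolinone/Methylisothiazolinone (MCI/MI),2.80,0.50,5.60,1,excluded
Myroxylon pereirae resin,6.50,1.10,5.90,1,included
Citral,1.20,0.20,6.00,1,included
Cinnamal,5.15,0.80,6.44,1,included
Potassium dichromate,5.40,0.80,6.75,1,excluded
Hydroxycitronellal,4.05,0.50,8.10,1,included
Carba mix,4.60,0.50,9.20,1,excluded
Ethylenediamine (dichloride),2.40,0.25,9.60,1,excluded
Geraniol,4.25,0.40,10.62,1,included
Wool alcohols,2.40,0.20,12.00,1,excluded
Neomycin sulfate,5.05,0.40,12.63,1,included
Caine mix,1.30,0.10,13.00,1,excluded
Methylchloroisothiazolinone (MCI),4.00,0.20,20.00,1,included
Cinnamic alcohol,8.30,0.30,27.77,1,included
Isopropyl myristate,0.20,0.00,NC,1,included
Benzyl alcohol,0.30,0.00,NC,1,included
Propyl gallate,0.70,0.00,NC,1,included
Triethanolamine,0.80,0.00,NC,1,included
Bronopol,1.20,0.00,NC,1,included
DMDM Hydantoin,1.35,0.00,NC,1,included
Butylhydroxyanisole (BHA),1.40,0.00,NC,1,included
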