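substance,hapten,cas,smiles,representative
Ammylcinnamyl alcohol,Ammylcinnamyl alcohol,101-85-9,OCC(=Cc1ccccc1)CCCCC,false
Benzocaine,Benzocaine,94-09-7,CCOC(=O)c1ccc(N)cc1,false
Benzyl alcohol,Benzyl alcohol,100-51-6,OCc1ccccc1,false
Benzyl salicylate,Benzyl salicylate,118-58-1,O=C(OCc1ccccc1)c1ccccc1O,false
Black rubber mix,N-isopropyl-N-phenyl parapheylenediamine,101-72-4,CC(C)Nc1ccc(Nc2ccccc2)cc1,false
Black rubber mix,N-cyclohexyl-N-phenyl paraphenylenediamine,101-87-1,C1CCC(CC1)Nc1ccc(Nc2ccccc2)cc1,false
Black rubber mix,N-biphenyl paraphenylenediamine,74-31-7,c1ccc(Nc2ccc(Nc3ccccc3)cc2)cc1,false
Butylhydroxyanisole (BHA),Butylhydroxyanisole,25013-16-5,COc1ccc(O)c(C(C)(C)C)c1,false
Bronopol,Bronopol,52-51-7,OCC(Br)(CO)[N+](=O)[O-],false
Cinnamal,Cinnamal,104-55-2,O=C/C=C/c1ccccc1,false
Cinnamic alcohol,Cinnamic alcohol,104-54-1,OC/C=C/c1ccccc1,false
Citral,Citral,5392-40-5,CC(C)=CCC/C(C)=C/C=O,false
Cocamidopropyl betaine,Cocamidopropyl betaine,61789-40-0,CCCCCCCCCCCC(=O)NCCC[N+](C)(C)CC(=O)[O-],true
Colophonium,Colophonium,8050-09-7,CC(C)C1=CC2=CCC3C(C)(CCCC3(C)C(=O)O)C2CC1,true
Diazolidynyl urea,Diazolidynyl Urea,78491-02-8,OCN1C(=O)N(CO)C(C1=O)N(CO)C(=O)NCO,false
DMDM Hydantoin,DMDM Hydantoin,6440-58-0,CC1(C)C(=O)N(CO)C(=O)N1CO,false
Epoxy resin,Epichlorohydrin,106-89-8,ClCC1CO1,false
Epoxy resin,"4,4'-Isopropylidenediphenol",80-05-7,CC(C)(c1ccc(O)cc1)c1ccc(O)cc1,false
Evernia prunastri extract,Evernia prunastri extract,90028-68-5,COc1cc(O)cc(C)c1C(=O)Oc1cc(C)c(C(=O)O)c(O)c1,true
Farnesol,Farnesol,4602-84-0,CC(C)=CCC/C(C)=C/CC/C(C)=C/CO,false
Formaldehyde,Formaldehyde,50-00-0,C=O,false
Geraniol,Geraniol,106-24-1,CC(C)=CCC/C(C)=C/CO,false
Hydroxycitronellal,Hydroxycitronellal,107-75-5,O=CCC(C)CCCC(C)(C)O,false
Imidazolidynyl urea,Imidazolidynyl urea,39236-46-9,OCN1C(=O)NC(C1=O)NC(=O)NCNC(=O)NC1NC(=O)N(CO)C1=O,false
Iodopropynyl butylcarbamate,Iodopropynyl butylcarbamate,55406-53-6,CCCCNC(=O)OCC#CI,false
Isopropyl myristate,Isopropyl myristate,110-27-0,CCCCCCCCCCCCCC(=O)OC(C)C,false
Lanolin,Lanolin,8006-54-0,CC(C)CCCC(C)C1CCC2C3CC=C4CC(O)CCC4(C)C3CCC12C,true
"Hydroxyisohexyl 3-cyclohexene carboxaldehyde (HICC, Lyral)",Hydroxyisohexyl 3-cyclohexene carboxaldehyde,31906-04-4,O=CC1CCC(=CC1)CCCC(C)(C)O,false
Mercapto mix,"2,'2-Benzothiazyl_disulfide",120-78-5,S(Sc1nc2ccccc2s1)c1nc2ccccc2s1,false
Mercapto mix,4-Morpholinyl-2-benzothiazyl disulfide,95-32-9,C1COCCN1SSc1nc2ccccc2s1,false
Mercapto mix,3_N-Cyclohexyl-2-benzothiazolesulfenamide,95-33-0,C1CCC(CC1)NSc1nc2ccccc2s1,false
Mercaptobenzothiazole,Mercaptobenzothiazole,149-30-4,Sc1nc2ccccc2s1,false
Methylchloroisothiazolinone (MCI),Methylchloroisothiazolinone,26172-55-4,CN1SC(Cl)=CC1=O,false
Methyldibromo Glutaronitrile (MDBGN),Methyldibromo glutaronitrile,35691-65-7,N#CC(Br)(CBr)CCC#N,false
Methylisothiazolinone (MI),Methylisothiazolinone,2682-20-4,CN1SC=CC1=O,false
Myroxylon pereirae resin,Myroxylon pereirae resin,8007-00-9,O=C(OCc1ccccc1)/C=C/c1ccccc1,true
Neomycin sulfate,Neomycin sulfate,1405-10-3,C1C(C(C(C(C1N)OC2C(C(C(C(O2)CN)O)O)N)OC3C(C(C(O3)CO)OC4C(C(C(C(O4)CN)O)O)N)O)O)N,false
Paraben mix,Methylparaben,99-76-3,COC(=O)c1ccc(O)cc1,false
Paraben mix,Bythylparaben,94-26-8,CCCCOC(=O)c1ccc(O)cc1,false
Paraben mix,Ethylparaben,120-47-8,CCOC(=O)c1ccc(O)cc1,false
Paraben mix,Propylparaben,94-13-3,CCCOC(=O)c1ccc(O)cc1,false
p-Phenylenediamine (PPD),p-Phenylenediamine,106-50-3,Nc1ccc(N)cc1,false
Propyl gallate,Propyl gallate,121-79-9,CCCOC(=O)c1cc(O)c(O)c(O)c1,false
Quaternium 15,Quaternium 15,4080-31-3,ClC=C/C[N+]12CN3CN(C1)CN(C2)C3.[Cl-],false
Quinoline mix,Quinoline,91-22-5,c1ccc2ncccc2c1,false
Quinoline mix,Chlorquinadol,72-80-0,Cc1ccc2c(Cl)cc(Cl)c(O)c2n1,false
Sorbitan sesquilate,Sorbitol,50-70-4,OCC(O)C(O)C(O)C(O)CO,false
Sorbitan sesquilate,Oleic acid,112-80-1,CCCCCCCC/C=C\CCCCCCCC(=O)O,false
Thimerosal,Thimerosal,54-64-8,CC[Hg]Sc1ccccc1C(=O)[O-].[Na+],false
Triethanolamine,Triethanolamine,102-71-6,OCCN(CCO)CCO,false
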