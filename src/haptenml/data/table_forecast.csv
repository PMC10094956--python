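hapten,iupac_name,cas,smiles,paper_call
Acetophenone azine,(E)-1-phenyl-N-[(E)-1-phenylethylideneamino]ethanimine,729-43-1,CC(=NN=C(C)c1ccccc1)c1ccccc1,0
Cyclamen aldehyde,2-methyl-3-(4-propan-2-ylphenyl)propanal,103-95-7,CC(C=O)Cc1ccc(C(C)C)cc1,1
Dibucaine,2-butoxy-N-[2-(diethylamino)ethyl]quinoline-4-carboxamide,85-79-0,CCCCOc1cc(C(=O)NCCN(CC)CC)c2ccccc2n1,0
"N,N-Dimethylacrylamide","N,N-dimethylprop-2-enamide",2680-03-7,CN(C)C(=O)C=C,1
Dimethylthiocarbamyl benzothiazole sulphide,"N,N-dimethylthiocarbamylbenzothiazole sulfide",3432-25-5,CN(C)C(=S)Sc1nc2ccccc2s1,1
Disperse Blue 106,2-(Ethyl(3-methyl-4-((5-nitrothiazol-2-yl)diazenyl)phenyl)amino)ethanol,68516-81-4,CCN(CCO)c1ccc(N=Nc2ncc([N+](=O)[O-])s2)c(C)c1,0
Disperse Blue 124,"2-[N-ethyl-3-methyl-4-[(5-nitro-1,3-thiazol-2-yl)diazenyl]anilino]ethyl acetate",15141-18-1,CCN(CCOC(C)=O)c1ccc(N=Nc2ncc([N+](=O)[O-])s2)c(C)c1,0
Geraniol hydroperoxide,"(2Z)-1-hydroperoxy-3,7-dimethylocta-2,6-dien-1-ol",n/a,OOC(O)/C=C(\C)CCC=C(C)C,1
Hexyl salicylate,hexyl 2-hydroxybenzoate,6259-76-3,CCCCCCOC(=O)c1ccccc1O,0
Isobornyl acrylate,"[(1R,2R,4R)-1,7,7-trimethyl-2-bicyclo[2.2.1]heptanyl] prop-2-enoate",5888-33-5,C=CC(=O)OC1CC2CCC1(C)C2(C)C,1
Lidocaine,"2-(diethylamino)-N-(2,6-dimethylphenyl)acetamide",137-58-6,CCN(CC)CC(=O)Nc1c(C)cccc1C,0
Neral,"(2Z)-3,7-dimethylocta-2,6-dienal",106-26-3,CC(C)=CCC/C(C)=C\C=O,1
Prenyl caffeate,"3-methylbut-2-enyl (E)-3-(3,4-dihydroxyphenyl)prop-2-enoate",118971-61-2,CC(C)=CCOC(=O)/C=C/c1ccc(O)c(O)c1,1
Tetracaine,2-(dimethylamino)ethyl 4-(butylamino)benzoate,94-24-6,CCCCNc1ccc(C(=O)OCCN(C)C)cc1,0
2-(thiocyanomethylthio) benzothiazole,"1,3-benzothiazol-2-ylsulfanylmethyl thiocyanate",21564-17-0,N#CSCSc1nc2ccccc2s1,0
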