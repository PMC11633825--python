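# Experimental proton transfer free energies from water (kcal/mol), transcribed
# from published compilations; "method" names the extrathermodynamic assumption
# used to split single-ion solvation energies.
solvent,method,value,unit,citation
acetonitrile,TATB,10.7,kcal/mol,tetraphenylarsonium-tetraphenylborate compilation
acetonitrile,CPA,5.7,kcal/mol,cluster-pair approximation compilation
acetonitrile,Rossini,10.8,kcal/mol,regression of computed vs experimental pKa (Rossini)
dmso,TATB,-4.6,kcal/mol,tetraphenylarsonium-tetraphenylborate compilation
dmso,CPA,-7.4,kcal/mol,cluster-pair approximation compilation
dmso,Rossini,-0.5,kcal/mol,regression of computed vs experimental pKa (Rossini)
ethanol,TATB,2.7,kcal/mol,tetraphenylarsonium-tetraphenylborate compilation
methanol,TATB,2.1,kcal/mol,tetraphenylarsonium-tetraphenylborate compilation
methanol,CPA,2.4,kcal/mol,cluster-pair approximation compilation
methanol,Rossini,0.0,kcal/mol,regression of computed vs experimental pKa (Rossini)
dmf,TATB,-3.4,kcal/mol,tetraphenylarsonium-tetraphenylborate compilation
formamide,TATB,,kcal/mol,no consensus value reported
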