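name	smiles	reported_closeness
Glypallichalcone	COC1=CC=C(C=C1)C(=O)/C=C/C2=C(C=C(C=C2)O)OC	0.473
Echinatin	COC1=C(C=CC(=C1)O)/C=C/C(=O)C2=CC=C(C=C2)O	0.512
Licochalcone B	COC1=C(C=CC(=C1O)O)/C=C/C(=O)C2=CC=C(C=C2)O	0.501
Licochalcone C	CC(=CCC1=C(C=CC(=C1OC)/C=C/C(=O)C2=CC=C(C=C2)O)O)C	0.378
Licochalcone D	CC(=CCC1=C(C=CC(=C1)C(=O)/C=C/C2=C(C(=C(C=C2)O)O)OC)O)C	0.343
Licochalcone E	C[C@H](C1=C(C=C(C(=C1)/C=C/C(=O)C2=CC=C(C=C2)O)OC)O)C(=C)C	0.445
Licochalcone F	CC(C1=C(C=CC(=C1OC)/C=C/C(=O)C2=CC=C(C=C2)O)O)C(=C)C	0.464
Licochalcone G	CC(C)(C=C)C1=C(C=C(C(=C1)/C=C/C(=O)C2=C(C=C(C=C2)O)O)OC)O	0.308
3,4,3′,4′-Tetrahydroxy-2-methoxychalcone	COC1=C(C=CC(=C1O)O)/C=C/C(=O)C2=CC(=C(C=C2)O)O	0.438
Licochalcone A	CC(C)(C=C)C1=C(C=C(C(=C1)/C=C/C(=O)C2=CC=C(C=C2)O)OC)O	0.357
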