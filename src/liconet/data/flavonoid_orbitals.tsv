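compound	homo_ev	lumo_ev	gap_ev
Licochalcone A	-5.72	-1.77	3.95
Licochalcone B	-5.67	-1.86	3.81
Licochalcone C	-5.67	-1.76	3.91
Licochalcone D	-5.63	-1.82	3.82
Licochalcone E	-5.50	-1.59	3.91
Licochalcone F	-5.76	-1.81	3.95
Licochalcone G	-5.54	-1.85	3.69
Glypallichalcone	-5.75	-1.77	3.99
Echinatin	-5.54	-1.67	3.87
3,4,3′,4′-Tetrahydroxy-2-methoxychalcone	-5.64	-1.73	3.91
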