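ligand	receptor
Rps19	C5ar1
Csf1	Csf1r
Il34	Csf1r
Cx3cl1	Cx3cr1
Ccl7	Ccr2
Lgals9	Ptprc
Cxcl16	Cxcr6
Cd86	Cd28
Tnf	Tnfrsf1b
Itgb2	Cd226
App	Cd74
Mif	Cd74
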