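id	name	formula	charge	dfg_prime	dfg_uncertainty
glucose	D-glucose	C6H12O6	0	-426.71	1.5
lactate	L-lactate	C3H5O3	-1	-313.70	1.3
pyruvate	pyruvate	C3H3O3	-1	-350.78	1.1
acetate	acetate	C2H3O2	-1	-247.82	0.8
butyrate	butyrate	C4H7O2	-1	-68.08	2.4
caproate	caproate (hexanoate)	C6H11O2	-1	111.68	3.6
H+	proton	H1	1	0.0	0.0
H2O	water	H2O1	0	-155.66	0.1
CO2	carbon dioxide (aq)	C1O2	0	-385.98	1.2
H2	dihydrogen (aq)	H2	0	99.13	1.0
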