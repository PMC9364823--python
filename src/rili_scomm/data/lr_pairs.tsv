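ligand	receptor
Cxcl16	Cxcr6
Ccl8	Ccr5
Adam28	Itga4
Fn1	Itgb7
Fn1	Itga4
Gnai2	Ccr5
Hp	Itgb2
Ccl21a	Cxcr3
Icam1	Itgb2
Icam1	Spn
Cxcl12	Cxcr4
Ccl2	Ccr2
Tgfb1	Tgfbr1
Il1b	Il1r1
Tnf	Tnfrsf1a
Vegfa	Kdr
Dll4	Notch1
Jag1	Notch2
Apoe	Ldlr
Cd274	Pdcd1
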