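phase	gene
S	Mcm5
S	Pcna
S	Tyms
S	Fen1
S	Mcm2
S	Mcm4
S	Rrm1
S	Ung
S	Gins2
S	Mcm6
S	Cdca7
S	Dtl
S	Prim1
S	Uhrf1
S	Hells
S	Rfc2
S	Rpa2
S	Nasp
S	Rad51ap1
S	Gmnn
S	Wdr76
S	Slbp
S	Ccne2
S	Ubr7
S	Pold3
S	Msh2
S	Atad2
S	Rad51
S	Rrm2
S	Cdc45
S	Cdc6
S	Exo1
S	Tipin
S	Dscc1
S	Blm
S	Casp8ap2
S	Usp1
S	Clspn
S	Pola1
S	Chaf1b
S	Brip1
S	E2f8
G2M	Hmgb2
G2M	Cdk1
G2M	Nusap1
G2M	Ube2c
G2M	Birc5
G2M	Tpx2
G2M	Top2a
G2M	Ndc80
G2M	Cks2
G2M	Nuf2
G2M	Cks1b
G2M	Mki67
G2M	Tmpo
G2M	Cenpf
G2M	Tacc3
G2M	Smc4
G2M	Ccnb2
G2M	Ckap2l
G2M	Ckap2
G2M	Aurkb
G2M	Bub1
G2M	Kif11
G2M	Anp32e
G2M	Tubb4b
G2M	Gtse1
G2M	Kif20b
G2M	Hjurp
G2M	Cdca3
G2M	Cdc20
G2M	Ttk
G2M	Kif2c
G2M	Rangap1
G2M	Ncapd2
G2M	Dlgap5
G2M	Cdca2
G2M	Cdca8
G2M	Ect2
G2M	Kif23
G2M	Hmmr
G2M	Aurka
G2M	Psrc1
G2M	Anln
G2M	Lbr
G2M	Ckap5
G2M	Cenpe
G2M	Nek2
G2M	G2e3
G2M	Gas2l3
G2M	Cbx5
G2M	Cenpa
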