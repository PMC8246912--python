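# Mouse orthologs of the canonical S-phase gene list (v1)
Mcm5
Pcna
Tyms
Fen1
Mcm2
Mcm4
Rrm1
Ung
Gins2
Mcm6
Cdca7
Dtl
Prim1
Uhrf1
Cenpu
Hells
Rfc2
Rpa2
Nasp
Rad51ap1
Gmnn
Wdr76
Slbp
Ccne2
Ubr7
Pold3
Msh2
Atad2
Rad51
Rrm2
Cdc45
Cdc6
Exo1
Tipin
Dscc1
Blm
Casp8ap2
Usp1
Clspn
Pola1
Chaf1b
Brip1
E2f8
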