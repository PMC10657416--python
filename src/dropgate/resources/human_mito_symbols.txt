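# Human mitochondrially encoded genes (HGNC symbols)
MT-ND1
MT-ND2
MT-ND3
MT-ND4
MT-ND4L
MT-ND5
MT-ND6
MT-CO1
MT-CO2
MT-CO3
MT-ATP6
MT-ATP8
MT-CYB
MT-RNR1
MT-RNR2
MT-TA
MT-TC
MT-TD
MT-TE
MT-TF
MT-TG
MT-TH
MT-TI
MT-TK
MT-TL1
MT-TL2
MT-TM
MT-TN
MT-TP
MT-TQ
MT-TR
MT-TS1
MT-TS2
MT-TT
MT-TV
MT-TW
MT-TY
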