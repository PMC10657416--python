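# Human mitochondrially encoded genes (Ensembl gene ids, protein-coding + rRNA)
ENSG00000198888
ENSG00000198763
ENSG00000198804
ENSG00000198712
ENSG00000228253
ENSG00000198899
ENSG00000198938
ENSG00000198840
ENSG00000212907
ENSG00000198886
ENSG00000198786
ENSG00000198695
ENSG00000198727
ENSG00000211459
ENSG00000210082
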