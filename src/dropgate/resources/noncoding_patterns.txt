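# Regex patterns (python re, case-sensitive) for symbols of non-protein-coding genes.
# Coding status from gene symbols is assigned as the complement of these patterns.
^LINC\d
^MIR\d
^MIRLET
^SNOR[DA]
^SNHG\d
^RNU\d
^RNY\d
^RNA5S
^RNVU
^RPPH1$
^RMRP$
^MALAT1$
^NEAT1$
^XIST$
^Xist$
^Malat1$
^Neat1$
.+-AS\d*$
^MT-RNR
^MT-T[A-Z]\d?$
^mt-Rnr
^mt-T[a-z]
^Mt-rnr
^Mt-t[a-z]
^mt-rnr
^mt-t[a-z]
^mt:lrRNA$
^mt:srRNA$
^mt:tRNA
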