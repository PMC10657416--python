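# Drosophila mitochondrially encoded genes (FlyBase symbols)
mt:ND1
mt:ND2
mt:ND3
mt:ND4
mt:ND4L
mt:ND5
mt:ND6
mt:CoI
mt:CoII
mt:CoIII
mt:ATPase6
mt:ATPase8
mt:Cyt-b
mt:lrRNA
mt:srRNA
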