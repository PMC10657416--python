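# Rat mitochondrially encoded genes (RGD symbols)
Mt-nd1
Mt-nd2
Mt-nd3
Mt-nd4
Mt-nd4l
Mt-nd5
Mt-nd6
Mt-co1
Mt-co2
Mt-co3
Mt-atp6
Mt-atp8
Mt-cyb
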