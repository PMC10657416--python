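# Zebrafish mitochondrially encoded genes (ZFIN symbols)
mt-nd1
mt-nd2
mt-nd3
mt-nd4
mt-nd4l
mt-nd5
mt-nd6
mt-co1
mt-co2
mt-co3
mt-atp6
mt-atp8
mt-cyb
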