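# Mouse mitochondrially encoded genes (MGI symbols)
mt-Nd1
mt-Nd2
mt-Nd3
mt-Nd4
mt-Nd4l
mt-Nd5
mt-Nd6
mt-Co1
mt-Co2
mt-Co3
mt-Atp6
mt-Atp8
mt-Cytb
mt-Rnr1
mt-Rnr2
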