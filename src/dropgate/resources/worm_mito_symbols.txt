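# C. elegans mitochondrially encoded genes (WormBase symbols)
nduo-1
nduo-2
nduo-3
nduo-4
nduo-5
nduo-6
ndfl-4
ctc-1
ctc-2
ctc-3
atp-6
ctb-1
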