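period	lineages	mutations
2	2	3
3	3	6
4	4	2
5	5	5
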