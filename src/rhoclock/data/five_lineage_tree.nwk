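((((a:2,b:3):2,c:0):6,d:0):3,e:0);
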