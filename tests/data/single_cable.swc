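# synthetic single straight cable along z
1 3 0 0 0 0.8 -1
2 3 0 0 10 0.8 1
3 3 0 0 20 0.8 2
4 3 0 0 30 0.8 3
5 3 0 0 40 0.8 4
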