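# synthetic toy arbor: soma, bifurcation, trifurcation
1 1 0 0 0 5 -1
2 3 0 0 6 1.2 1
3 3 0 0 14 1.0 2
4 3 5 0 20 0.8 3
5 3 -5 0 20 0.8 3
6 3 5 0 30 0.6 4
7 3 10 3 26 0.6 4
8 3 10 -3 26 0.6 4
9 4 0 7 0 1.0 1
10 4 0 15 0 0.9 9
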