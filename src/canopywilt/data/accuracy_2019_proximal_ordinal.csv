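# Published 2019 proximal validation contingency matrix: visual wilting
# score (rows) vs model-estimated score (columns).
visual,0,1,2,3,4,5
0,69,0,0,2,0,0
1,10,0,0,2,0,0
2,1,0,0,12,1,0
3,1,0,0,42,6,0
4,0,0,0,14,7,0
5,0,0,0,0,0,0
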