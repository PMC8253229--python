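# Published 2018 proximal contingency matrix: visual wilting score (rows)
# vs image-derived score (columns); scores 4-5 absent from the training set.
visual,0,1,2,3
0,0,4,0,0
1,0,52,20,0
2,0,20,41,4
3,0,0,20,6
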