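# Published 2019 aerial validation turgid/wilted contingency matrix.
visual,turgid,wilted
turgid,86,4
wilted,5,73
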