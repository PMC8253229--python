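# Published 2018 aerial turgid/wilted contingency matrix.
visual,turgid,wilted
turgid,106,10
wilted,11,41
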