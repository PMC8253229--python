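# Published 2018 proximal turgid/wilted contingency matrix (visual rows,
# estimated columns).
visual,turgid,wilted
turgid,55,21
wilted,17,74
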