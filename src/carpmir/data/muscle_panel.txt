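miR-1
miR-21
miR-23a
miR-24
miR-26a
miR-27a
miR-133a-3p
miR-181a-5p
miR-206
miR-214
miR-222
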