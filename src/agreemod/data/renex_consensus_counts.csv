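RENEX,consensus,count
non-obstructed,non-obstructed,101
non-obstructed,equivocal,7
non-obstructed,obstructed,1
equivocal,non-obstructed,14
equivocal,equivocal,13
equivocal,obstructed,2
obstructed,non-obstructed,5
obstructed,equivocal,9
obstructed,obstructed,33
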