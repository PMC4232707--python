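gA	A
gB	B
gC	C
gD	D
gE	E
gF	F
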