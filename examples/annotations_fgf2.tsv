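first	last	label
25	29	N-terminal tail end
66	71	b4 strand / b4-b5 loop
107	112	b8-b9 turn
128	144	b10-b12 loop
154	155	C-terminal tail
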