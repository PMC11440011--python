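a	b	c	d
79	11617	13673	7499604
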