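stratum	a	b	c	d
Female	44	6716	6770	3780862
Male	30	4568	5066	2663901
Unspecified sex	5	404	1876	1071339
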