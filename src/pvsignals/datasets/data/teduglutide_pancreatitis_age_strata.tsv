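stratum	a	b	c	d
Less than 18	2	1502	528	250587
18-24	1	195	295	153402
25-64	31	3994	4988	2180515
65 and older	11	2278	2532	1605348
Unspecified age	34	3719	5369	3326250
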