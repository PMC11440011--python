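characteristic	category	n
Age (in years)	Less than 18	1629
Age (in years)	18-24	193
Age (in years)	25-64	3920
Age (in years)	65 and older	2229
Sex	Female	6723
Sex	Male	4568
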