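sample_id	genotype	sex	timepoint	batch
s1	WT	F	9m	B9m
s2	WT	F	9m	B9m
s3	WT	M	9m	B9m
s4	WT	M	9m	B9m
s5	FAD5X	F	9m	B9m
s6	FAD5X	F	9m	B9m
s7	FAD5X	M	9m	B9m
s8	FAD5X	M	9m	B9m
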