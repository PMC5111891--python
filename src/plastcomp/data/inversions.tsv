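region	location	length	stem_arm_length
petA-psbJ	Intergenic	14	27
rpl16	Intron	3	19
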