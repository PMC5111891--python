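feature	h_ammodendron	h_persicum	s_oleracea	b_vulgaris
total_length	151570	151586	150725	149635
lsc_length	84214	84217	82719	83057
ir_length	24171	24177	25073	24439
ssc_length	19014	19015	17860	17701
gc_total_percent	36.6	36.6	36.9	36.4
gc_lsc_percent	34.4	34.5	34.8	34.1
gc_ir_percent	43.0	43.0	42.7	42.2
gc_ssc_percent	29.7	29.7	29.8	29.2
n_genes	112	112	112	113
n_protein_genes	78	78	78	79
n_trna_genes	30	30	30	30
n_rrna_genes	4	4	4	4
n_pseudogenes	2	2	2	1
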