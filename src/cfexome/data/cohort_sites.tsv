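patient	tumor_type	n_retained_variants	plasma_ctdna_fraction	p_value
SWE-54	prostate	27	0.001	0.265
BC_A	breast	26	0	1
BC_B	breast	184	0	1
BC_C	breast	17	0	1
BC_D	breast	245	0.003	1.16e-18
BC_E	breast	20	0	1
BC_F	breast	82	0	1
BC_G	breast	47	0	1
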