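id	name	family	is_anchor
Rn_rhodopsin	Rn-rhodopsin	ciliary	true
Sp_opsin_1	Sp-opsin 1	ciliary	false
Sp_opsin_2	Sp-opsin 2	basal-branch	false
Sp_opsin_5	Sp-opsin 5	basal-branch	false
Sp_opsin_3_1	Sp-opsin 3.1	Go	false
Sp_opsin_3_2	Sp-opsin 3.2	Go	false
Sp_opsin_4	Sp-opsin 4	rhabdomeric	false
Sp_opsin_6	Sp-opsin 6	peropsin	false
Sp_opsin_7	Sp-opsin 7	RGR	false
Sp_opsin_8	Sp-opsin 8	neuropsin	false
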