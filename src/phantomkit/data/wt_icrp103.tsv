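# ICRP Publication 103 tissue weighting factors.
# role=weighted: tissue carries its own w_T.
# role=remainder: member of the remainder set; the remainder w_T is shared
# as the arithmetic mean of member equivalent doses (sex-specific members:
# prostate counts for the male map, uterus for the female map).
tissue	w_T	role	sex
bone_marrow	0.12	weighted	both
colon	0.12	weighted	both
lung	0.12	weighted	both
stomach	0.12	weighted	both
breast	0.12	weighted	both
remainder	0.12	weighted	both
gonads	0.08	weighted	both
bladder	0.04	weighted	both
oesophagus	0.04	weighted	both
liver	0.04	weighted	both
thyroid	0.04	weighted	both
bone_surface	0.01	weighted	both
brain	0.01	weighted	both
salivary_glands	0.01	weighted	both
skin	0.01	weighted	both
adrenals	0.0	remainder	both
extrathoracic_region	0.0	remainder	both
gall_bladder	0.0	remainder	both
heart	0.0	remainder	both
kidneys	0.0	remainder	both
lymphatic_nodes	0.0	remainder	both
muscle	0.0	remainder	both
oral_mucosa	0.0	remainder	both
pancreas	0.0	remainder	both
prostate	0.0	remainder	male
small_intestine	0.0	remainder	both
spleen	0.0	remainder	both
thymus	0.0	remainder	both
uterus	0.0	remainder	female
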