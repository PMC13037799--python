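# Default material library: elemental mass fractions and densities [g/cm3].
# Compositions follow the usual ICRU/ICRP-style reference soft/skeletal
# tissue recipes restricted to the 13-element set used by this toolkit
# (trace elements folded into the nearest listed element, fractions
# renormalized to 1).
material	density	H	C	N	O	Na	Mg	P	S	Cl	K	Ca	Fe	I
air	0.0012	0	0.0001	0.7681	0.2318	0	0	0	0	0	0	0	0	0
water	1.000	0.1119	0	0	0.8881	0	0	0	0	0	0	0	0	0
soft_tissue	1.05	0.102	0.143	0.034	0.708	0.002	0	0.003	0.003	0.002	0.003	0	0	0
skin	1.09	0.100	0.204	0.042	0.645	0.002	0	0.001	0.002	0.003	0.001	0	0	0
adipose	0.95	0.114	0.598	0.007	0.278	0.001	0	0	0.001	0.001	0	0	0	0
breast	1.02	0.106	0.332	0.030	0.527	0.001	0	0.001	0.002	0.001	0	0	0	0
hard_bone	1.92	0.034	0.155	0.042	0.435	0.001	0.002	0.103	0.003	0	0	0.225	0	0
active_marrow	1.03	0.105	0.414	0.034	0.439	0	0	0.001	0.002	0.002	0.002	0	0.001	0
inactive_marrow	0.98	0.115	0.644	0.007	0.231	0.001	0	0	0.001	0.001	0	0	0	0
eyeball	1.05	0.097	0.183	0.054	0.660	0.001	0	0.001	0.003	0.001	0	0	0	0
lens	1.07	0.096	0.195	0.057	0.646	0.001	0	0.001	0.003	0.001	0	0	0	0
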