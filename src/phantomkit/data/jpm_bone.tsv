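# Per-anatomical-region skeletal component masses, adult male model [kg]
region	active_marrow	inactive_marrow	hard_bone	endosteum	total
Humeri, upper half	0.024	0.086	0.158	0.008	0.277
Humeri, lower half	0.000	0.067	0.149	0.010	0.226
Ulnae and radii	0.000	0.072	0.152	0.014	0.238
Wrist and hand bones	0.000	0.060	0.107	0.008	0.176
Clavicles	0.008	0.010	0.040	0.002	0.060
Cranium	0.077	0.224	1.059	0.073	1.432
Femora, upper half	0.071	0.132	0.382	0.039	0.623
Femora, lower half	0.000	0.292	0.444	0.027	0.763
Tibiae, fibiae, patellae	0.000	0.437	0.652	0.097	1.185
Ankle and foot bones	0.000	0.279	0.410	0.028	0.717
Mandible	0.007	0.028	0.128	0.002	0.165
Pelvis	0.185	0.152	0.451	0.045	0.834
Ribs	0.157	0.122	0.338	0.026	0.643
Scapulae	0.029	0.087	0.221	0.009	0.345
Cervical vertebrae	0.038	0.009	0.101	0.010	0.157
Thoracic vertebrae	0.157	0.005	0.218	0.024	0.404
Lumbar vertebrae	0.120	0.042	0.192	0.021	0.375
Sacrum	0.097	0.008	0.103	0.018	0.226
Sternum	0.031	0.009	0.044	0.005	0.088
Os hyoideum	0.001	0.000	0.002	0.000	0.003
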