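# Per-anatomical-region skeletal component masses, adult female model [kg]
region	active_marrow	inactive_marrow	hard_bone	endosteum	total
Humeri, upper half	0.019	0.071	0.135	0.006	0.231
Humeri, lower half	0.000	0.037	0.096	0.007	0.140
Ulnae and radii	0.000	0.059	0.113	0.010	0.183
Wrist and hand bones	0.000	0.029	0.035	0.006	0.070
Clavicles	0.006	0.005	0.022	0.002	0.035
Cranium	0.060	0.221	0.987	0.056	1.322
Femora, upper half	0.055	0.118	0.335	0.030	0.537
Femora, lower half	0.000	0.187	0.299	0.021	0.507
Tibiae, fibiae, patellae	0.000	0.357	0.527	0.073	0.957
Ankle and foot bones	0.000	0.177	0.245	0.021	0.443
Mandible	0.006	0.016	0.119	0.001	0.143
Pelvis	0.144	0.071	0.295	0.034	0.544
Ribs	0.122	0.075	0.237	0.020	0.454
Scapulae	0.022	0.042	0.122	0.007	0.193
Cervical vertebrae	0.030	0.003	0.057	0.008	0.097
Thoracic vertebrae	0.119	0.000	0.136	0.018	0.273
Lumbar vertebrae	0.093	0.025	0.133	0.016	0.267
Sacrum	0.075	0.053	0.105	0.014	0.247
Sternum	0.024	0.011	0.027	0.004	0.066
Os hyoideum	0.000	0.001	0.002	0.000	0.003
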