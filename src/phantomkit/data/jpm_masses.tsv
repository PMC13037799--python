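# Organ/tissue/content masses of the adult male mesh model [kg]
organ	mass_kg
Adipose	17.386
Adrenal	0.014
Brain	1.470
Breast	0.022
Bronchi	0.011
Colon	0.330
Colon content	0.360
Endosteum	0.466
Esophagus	0.040
ET regions	0.004
Eyeball	0.015
Gall bladder	0.008
Gall bladder content	0.050
Hard bone	5.351
Heart	0.380
Heart content	0.400
Kidney	0.320
Lens	0.0004
Liver	1.600
Lung	1.200
Lymphatic tissue	0.220
Marrow (active)	1.001
Marrow (inactive)	2.121
Muscle	27.429
Oral mucosa	0.00015
Pancreas	0.130
Prostate	0.012
Salivary gland	0.082
Skin	2.411
Small intestine	0.590
Small intestine content	0.350
Spleen	0.140
Stomach	0.140
Stomach content	0.240
Tooth	0.059
Testis	0.037
Thymus	0.030
Thyroid	0.019
Tongue	0.067
Trachea	0.009
Urinary bladder	0.040
Urinary bladder content	0.100
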