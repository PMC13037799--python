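# Organ/tissue/content masses of the adult female mesh model [kg]
organ	mass_kg
Adipose	15.048
Adrenal	0.013
Brain	1.320
Breast	0.300
Bronchi	0.012
Colon	0.260
Colon content	0.280
Endosteum	0.352
Esophagus	0.030
ET regions	0.002
Eyeball	0.012
Gall bladder	0.006
Gall bladder content	0.038
Hard bone	4.027
Heart	0.300
Heart content	0.320
Kidney	0.280
Lens	0.0003
Liver	1.400
Lung	0.910
Lymphatic tissue	0.170
Marrow (active)	0.775
Marrow (inactive)	1.557
Muscle	20.704
Oral mucosa	0.0001
Ovary	0.011
Pancreas	0.110
Salivary gland	0.062
Skin	1.807
Small intestine	0.450
Small intestine content	0.270
Spleen	0.120
Stomach	0.110
Stomach content	0.180
Tooth	0.045
Thymus	0.029
Thyroid	0.017
Tongue	0.051
Trachea	0.007
Urinary bladder	0.030
Urinary bladder content	0.085
Uterus	0.070
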