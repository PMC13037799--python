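# Adult Japanese population-average organ masses [kg]; blank = no published average
organ	male_kg	female_kg
Adipose	13.900	15.200
Adrenal	0.014	0.013
Brain	1.470	1.320
Breast	0.022	0.300
Colon	0.330	0.260
Colon content	0.360	0.280
Esophagus	0.040	0.030
Eyeball	0.015	0.012
Gall bladder	0.008	0.006
Gall bladder content	0.050	0.038
Hard bone	4.500	3.400
Heart	0.380	0.300
Heart content	0.400	0.320
Kidney	0.320	0.280
Lens	0.0004	0.0003
Liver	1.600	1.400
Lung	1.200	0.910
Lymphatic tissue	0.220	0.170
Marrow (active)	1.000	0.780
Marrow (inactive)	1.300	0.990
Muscle	27.500	20.790
Ovary		0.011
Pancreas	0.130	0.110
Prostate	0.012
Salivary gland	0.082	0.062
Skin	2.400	1.800
Small intestine	0.590	0.450
Small intestine content	0.350	0.270
Spleen	0.140	0.120
Stomach	0.140	0.110
Stomach content	0.240	0.180
Tooth	0.045	0.034
Testis	0.037
Thymus	0.030	0.029
Thyroid	0.019	0.017
Tongue	0.067	0.051
Trachea	0.009	0.007
Urinary bladder	0.040	0.030
Urinary bladder content	0.100	0.085
Uterus		0.070
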