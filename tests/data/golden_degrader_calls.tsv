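species	tier	transcribed_ecs	max_prevalence
Species001	prevalent_versatile	3.2.1.165;3.2.1.18;3.2.1.51;3.2.1.52	1.0
Species002	prevalent_versatile	3.2.1.23;3.2.1.96	1.0
Species003	prevalent_versatile	3.2.1.49;3.2.1.50	1.0
Species005	encoder		
Species006	prevalent_versatile	3.2.1.165;3.2.1.22;3.2.1.23;3.2.1.52;3.2.1.97	0.916667
Species007	prevalent_versatile	3.2.1.18;3.2.1.23;3.2.1.51;3.2.1.96	1.0
Species008	encoder		
Species009	encoder		
Species011	prevalent_versatile	3.2.1.22;3.2.1.50;3.2.1.51	1.0
Species012	prevalent_versatile	3.2.1.165;3.2.1.18;3.2.1.23;3.2.1.96	1.0
Species013	encoder		
Species014	encoder		
Species015	encoder		
Species016	prevalent_versatile	3.2.1.23;3.2.1.49;3.2.1.52;3.2.1.97	1.0
Species017	prevalent_versatile	3.2.1.23;3.2.1.52	1.0
Species018	encoder		
Species020	encoder		
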