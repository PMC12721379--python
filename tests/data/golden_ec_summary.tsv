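ec	name	prevalence	mean_cpm	n_species	prevalent
3.1.6.14	N-acetylglucosamine-6-sulfatase	0.0	0.0	0	False
3.2.1.165	Exo-1,4-beta-D-glucosaminidase	1.0	32.84970573814959	3	True
3.2.1.18	Exo-alpha-sialidase	1.0	30.492764476569743	3	True
3.2.1.22	Alpha-galactosidase	1.0	21.574154275657552	2	True
3.2.1.23	Beta-galactosidase	1.0	61.49820826400247	6	True
3.2.1.49	Alpha-N-acetylgalactosaminidase	1.0	21.18736537808494	2	True
3.2.1.50	Alpha-N-acetylglucosaminidase	1.0	22.623968013933165	2	True
3.2.1.51	Alpha-L-fucosidase	1.0	35.61995734050658	3	True
3.2.1.52	Beta-N-acetylhexosaminidase	1.0	42.50406473994138	4	True
3.2.1.96	Endo-beta-N-acetylglucosaminidase	1.0	28.96470427999735	3	True
3.2.1.97	Endo-alpha-N-acetylgalactosaminidase	1.0	20.07953976079474	2	True
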