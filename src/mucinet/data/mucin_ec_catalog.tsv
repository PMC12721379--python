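# mucinet default catalog of mucin-glycan-degradation enzyme commission numbers
# detectable entries of the curated mucin CAZyme list; gh_families are the CAZy
# glycoside hydrolase families canonically associated with each activity
ec_id	name	enzyme_class	gh_families	versatility_excluded	active
3.1.6.14	N-acetylglucosamine-6-sulfatase	sulfatase		False	False
3.2.1.165	Exo-1,4-beta-D-glucosaminidase	glycosyl_hydrolase	GH9;GH35	False	True
3.2.1.18	Exo-alpha-sialidase	glycosyl_hydrolase	GH33	False	True
3.2.1.22	Alpha-galactosidase	glycosyl_hydrolase	GH27;GH36;GH97;GH110	True	True
3.2.1.23	Beta-galactosidase	glycosyl_hydrolase	GH2;GH35;GH42;GH59	True	True
3.2.1.49	Alpha-N-acetylgalactosaminidase	glycosyl_hydrolase	GH27;GH36;GH109	False	True
3.2.1.50	Alpha-N-acetylglucosaminidase	glycosyl_hydrolase	GH89	False	True
3.2.1.51	Alpha-L-fucosidase	glycosyl_hydrolase	GH29;GH95	False	True
3.2.1.52	Beta-N-acetylhexosaminidase	glycosyl_hydrolase	GH20;GH84	False	True
3.2.1.96	Endo-beta-N-acetylglucosaminidase	glycosyl_hydrolase	GH18;GH85	False	True
3.2.1.97	Endo-alpha-N-acetylgalactosaminidase	glycosyl_hydrolase	GH101;GH129	False	True
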