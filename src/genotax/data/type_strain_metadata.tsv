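species	type_strain	year_published
B. japonicum	USDA 6	1982
B. elkanii	USDA 76	1992
B. liaoningense	NBRC 100396	1995
B. betae	PL7HG1	2004
B. huanghuaihaiense	CB3035	2011
B. diazoefficiens	USDA 110	2014
B. ottawaense	OO99	2014
B. niftali	CNPSo 3448	2019
B. barranii	144S4	2022
B. xenonodulans	14AB	2023
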