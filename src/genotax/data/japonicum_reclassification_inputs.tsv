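strain	accession	ani_vs_reference_type	best_match_species	best_match_ani	ddh_estimate
USDA 135	GCF_000472945.1	88	B. liaoningense	100	99.30
USDA 124	GCA_000374205.1	90	B. huanghuaihaiense	98	78.10
USDA 4	GCA_024170865.1	90	B. ottawaense	99	92.80
USDA 51	GCA_025962335.1	90	B. ottawaense	99	92.80
USDA 52	GCA_025962315.1	90	B. ottawaense	99	92.80
USDA 53	GCA_025962325.1	90	B. ottawaense	99	92.80
USDA 54	GCA_025962375.1	90	B. ottawaense	99	92.80
USDA 55	GCA_025962395.1	90	B. ottawaense	99	92.80
USDA 106	GCA_025961105.1	90	B. ottawaense	99	92.80
USDA 20	GCA_024171125.1	90	B. diazoefficiens	100	100.00
USDA 21	GCA_024171105.1	90	B. diazoefficiens	100	99.90
USDA 30	GCA_024171185.1	90	B. diazoefficiens	100	99.80
USDA 36	GCA_025962255.1	90	B. diazoefficiens	99	89.40
USDA 44	GCA_025962295.1	90	B. diazoefficiens	99	89.40
USDA 62	GCA_025962455.1	90	B. diazoefficiens	99	89.00
USDA 64	GCA_025962445.1	90	B. diazoefficiens	100	99.80
USDA 91	GCA_025962555.1	90	B. diazoefficiens	99	88.90
USDA 92	GCA_025960915.1	90	B. diazoefficiens	100	99.80
USDA 96	GCA_025962515.1	90	B. diazoefficiens	100	99.80
USDA 300	GCA_017831985.1	91	B. diazoefficiens	99	91.10
USDA 500	GCA_017831945.1	90	B. diazoefficiens	100	97.30
USDA 11	GCA_024171285.1	84	B. elkanii	99	90.40
USDA 15	GCA_024170535.1	84	B. elkanii	99	94.60
DN3	GCA_041357655.1	88
22	GCA_024171145.1	87
in8p8	GCA_000426845.1	87
is5	GCA_000421305.1	87
MAG21	GCA_041987565.1	87
SZCCT0148	GCA_018129985.1	87
SZCCT0153	GCA_018129995.1	89
SZCCT0231	GCA_018130245.1	88
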